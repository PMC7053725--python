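"""Scoring PubTator-annotated abstracts with a trained model.

Trains a shallow-linguistic-kernel model on a synthetic labeled corpus, then
ingests a small PubTator-format block (title/abstract lines plus tab-separated
Chemical and Gene annotations), enumerates the sentence-bounded candidate
pairs, and scores them. Real deployments would swap in a real dependency
parser backend and a model trained on curated data; the flow is identical.
"""

from cpirex.corpus import parse_pubtator
from cpirex.pipeline import predict_corpus, train_model
from cpirex.sl_kernel import SLParams
from cpirex.synthetic import SyntheticConfig, generate_corpus

train_corpus = generate_corpus(
    SyntheticConfig(
        n_docs=150, sentences_per_doc=2,
        p_verb_given_pos=0.9, p_verb_given_neg=0.1, seed=5,
    )
)
model = train_model(train_corpus, "sl", SLParams(n=3, w=1))
print(
    f"trained SL model on {len(model.classifier.training_instance_ids)} "
    "labeled pairs"
)

PUBTATOR = """\
101|t|Aspirin inhibits COX-2 in endothelial cells.
101|a|In contrast, salicylate did not alter P2Y12 levels.
101\t0\t7\tAspirin\tChemical\tCID2244
101\t17\t22\tCOX-2\tGene\t5743
101\t58\t68\tsalicylate\tChemical\tCID338
101\t83\t88\tP2Y12\tGene\t64805
"""

corpus = parse_pubtator(PUBTATOR)
records = predict_corpus(model, corpus, allow_fixture_parses=True)
print(f"\n{len(records)} candidate pair(s) from the abstract:")
for r in records:
    verdict = "functional" if r.predicted == 1 else "not functional"
    print(
        f"  {r.compound_surface} - {r.protein_surface} "
        f"(sentence {r.sent_id}): score {r.score:+.3f} -> {verdict}"
    )
print(
    "\nPairs are sentence-bounded: the compound of one sentence is never "
    "paired with the protein of another. Scores are signed distances to the "
    "decision boundary; the sign at the model threshold gives the verdict."
)
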