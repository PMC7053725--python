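"""Document-wise cross-validation of both kernels on a synthetic benchmark.

Generates a seeded corpus whose positives carry a learnable surface signal
(class-correlated interaction verbs plus a marker token between the pair),
then runs 10-fold document-wise CV for the shallow linguistic kernel
(n-gram/window features, SVC) and the all-paths graph kernel (dependency-walk
features, RLS). Folds split documents, never pairs of one document, to avoid
leaking near-duplicate sentences. The stratified rows recompute the same
pooled scores on the verb-enclosing (IV) and no-verb (NIV) subsets.
"""

from cpirex.apg_kernel import APGParams
from cpirex.evaluation import (
    cross_validate,
    document_folds,
    evaluate_pooled,
    stratify_by_verb,
)
from cpirex.sl_kernel import SLParams
from cpirex.synthetic import SyntheticConfig, generate_corpus

corpus = generate_corpus(
    SyntheticConfig(
        n_docs=200, sentences_per_doc=2,
        p_verb_given_pos=0.9, p_verb_given_neg=0.1, seed=11,
    )
)
counts = corpus.counts
print(
    f"corpus: {len(corpus.documents)} documents, {counts.sentences} sentences, "
    f"{counts.positive} positive / {counts.negative} negative pairs\n"
)

split = document_folds(corpus, k=10, seed=3)
header = f"{'kernel':22s} {'rec':>6s} {'spec':>6s} {'prec':>6s} {'F1':>6s} {'AUC':>6s}"
print(header)


def row(name, report):
    r = report.rounded()
    print(
        f"{name:22s} {r['recall']:6.1f} {r['specificity']:6.1f} "
        f"{r['precision']:6.1f} {r['f1']:6.1f} "
        f"{r['auc'] if r['auc'] is not None else float('nan'):6.1f}"
    )


for kind, params in (("sl", SLParams(n=3, w=1)), ("apg", APGParams(c=0.25))):
    scored = cross_validate(corpus, kind, params, split=split)
    row(kind, evaluate_pooled(scored))
    iv, niv = stratify_by_verb(scored)
    if iv:
        row(f"  {kind} IV subset", iv)
    if niv:
        row(f"  {kind} NIV subset", niv)

print(
    "\nAUC well above 90 on the planted signal shows both kernels recover "
    "the between-entity lexical evidence; metrics are percentages over the "
    "pooled test folds."
)
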