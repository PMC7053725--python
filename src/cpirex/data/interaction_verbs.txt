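# Default interaction-verb lemma list (curated).
# One lemma per line; lines starting with '#' are comments.
# Covers the verb classes used to describe functional compound-protein
# relations: direct physical interaction, positive/negative regulation,
# enzymatic action, transport and complex formation.
abolish
abrogate
accelerate
activate
affect
agonize
alter
amplify
antagonize
attenuate
augment
bind
block
boost
catalyze
cleave
competes
complex
conjugate
convert
counteract
deactivate
decrease
degrade
dephosphorylate
deplete
depress
derepress
diminish
disrupt
downregulate
elevate
elicit
enhance
evoke
exacerbate
facilitate
hydrolyze
impair
impede
inactivate
increase
induce
influence
inhibit
initiate
interact
interfere
ligate
lower
mediate
metabolize
modify
modulate
neutralize
oxidize
perturb
phosphorylate
potentiate
prevent
promote
protect
raise
reduce
regulate
release
repress
restore
reverse
sensitize
sequester
stabilize
stimulate
suppress
synergize
target
transactivate
transform
transport
trigger
ubiquitinate
upregulate
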