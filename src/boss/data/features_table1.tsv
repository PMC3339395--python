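# Relation feature lexicon: 51 trigger-verb lemmas across 10 relation types.
# Columns: lemma <TAB> relation_type <TAB> origin
# origin marks whether the lemma came from corpus verb-frequency screening
# or from the relation-type ontology augmentation; the flags are advisory.
downregulate	NEGATIVE	ontology
inhibit	NEGATIVE	frequency
suppress	NEGATIVE	frequency
repress	NEGATIVE	frequency
interfere	NEGATIVE	ontology
inactivate	FULL-STOP	ontology
halt	FULL-STOP	ontology
block	FULL-STOP	frequency
limit	FULL-STOP	frequency
restrict	FULL-STOP	frequency
kill	FULL-STOP	frequency
unbind	BREAK-DOWN	ontology
depolymerize	BREAK-DOWN	ontology
disrupt	BREAK-DOWN	frequency
cleave	BREAK-DOWN	frequency
disassemble	BREAK-DOWN	ontology
decrease	DECREASE	frequency
diminish	DECREASE	frequency
reduce	DECREASE	frequency
increase	INCREASE	frequency
enrich	INCREASE	frequency
initiate	START	frequency
activate	START	frequency
promote	START	frequency
acetylate	ADDITION	ontology
add	ADDITION	frequency
phosphorylate	ADDITION	ontology
assemble	ASSEMBLY	ontology
cross-link	ASSEMBLY	ontology
attach	ASSEMBLY	frequency
polymerize	ASSEMBLY	ontology
bind	ASSEMBLY	frequency
integrate	ASSEMBLY	ontology
modulate	UNSPECIFIED	ontology
control	UNSPECIFIED	frequency
regulate	UNSPECIFIED	frequency
interact	UNSPECIFIED	frequency
disseminate	UNSPECIFIED	ontology
inherit	UNSPECIFIED	ontology
modify	UNSPECIFIED	frequency
stabilize	UNSPECIFIED	frequency
isolate	UNSPECIFIED	frequency
catalyze	POSITIVE	ontology
upregulate	POSITIVE	ontology
stimulate	POSITIVE	frequency
mediate	POSITIVE	frequency
accelerate	POSITIVE	ontology
amplify	POSITIVE	ontology
elevate	POSITIVE	ontology
enhance	POSITIVE	frequency
enlarge	POSITIVE	ontology
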