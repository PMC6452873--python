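"""Packaged worked-example data: the key-mutation table of the study system.

Five ALE substrate conditions on which *E. coli* K-12 MG1655 evolved growth,
the enzyme gene each underground-metabolism simulation predicted as the
mutational target, and the genes / regulatory elements actually mutated in
evolved clones shortly after weaning.  Regulatory elements (a repressor, a
transcription factor, intergenic promoter regions) are credited to the
gene(s) they directly regulate via ``REGULATOR_MAP``.

Expected outcome when matched: hits in 4 of the 5 conditions, D-arabinose
being the miss — there the evolved clones mutated *fucR*, the activator of
the *fuc* operon, whose promiscuous route was absent from the underground
reaction database used for prediction.
"""

from __future__ import annotations

CONDITIONS = [
    "D-lyxose",
    "D-2-deoxyribose",
    "D-arabinose",
    "m-tartrate",
    "monomethyl-succinate",
]

#: Enzyme gene predicted per condition by single-underground-reaction addition.
PREDICTED_GENES: dict[str, set[str]] = {
    "D-lyxose": {"yihS"},
    "D-2-deoxyribose": {"rbsK"},
    "D-arabinose": {"rbsK"},  # no fuc-route prediction available to the model
    "m-tartrate": {"dmlA"},
    "monomethyl-succinate": {"ybfF"},
}

#: Genes or regulatory elements mutated in evolved clones after weaning.
MUTATED_GENES: dict[str, set[str]] = {
    "D-lyxose": {"yihS", "yihW"},
    "D-2-deoxyribose": {"rbsK", "rbsR"},
    "D-arabinose": {"fucR"},
    "m-tartrate": {"dmlA", "dmlR/dmlA-intergenic"},
    "monomethyl-succinate": {"ybfF/seqA-intergenic"},
}

#: Direct regulatory credit: mutated element -> gene(s) it regulates.
REGULATOR_MAP: dict[str, set[str]] = {
    "rbsR": {"rbsK"},                      # rbs operon repressor
    "yihW": {"yihS"},                      # yih cluster regulator
    "dmlR/dmlA-intergenic": {"dmlA"},      # dmlRp3 promoter region
    "ybfF/seqA-intergenic": {"ybfF"},      # ybfFp1 promoter region
    "fucR": {"fucA", "fucI", "fucK", "fucO", "fucP"},  # fuc operon activator
}
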