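"""Published evidence tuples for nine experimentally characterized proteins.

The nine transporter genes that were synthesized and assayed in the study
this pipeline reproduces (one SbmA/BacA, six BclA including a former
*Mycobacterium* BacA, one BclA-like Clade B protein and one ExsE) come
with printed evidence tuples — preliminary HMM label, phylogeny clade and
SSN cluster — and a printed final classification.  They serve as a worked
example of the rule engine: feeding the tuples through
:func:`bacascan.classify.apply_rules` must reproduce the final calls.

Printed cluster compositions used for the component profiles: the BacA
cluster holds 71 proteins, all HMM-labeled SbmA/BacA; the main BclA
cluster holds 133 proteins of which 46 carry the *Mycobacterium* BacA
label; the cyanobacterial BclA cluster holds 44 proteins, 43 labeled
BclA or *Mycobacterium* BacA.
"""

from __future__ import annotations

from .classify import ComponentProfile, EvidenceRow

# cluster ids follow the published numbering; sizes/compositions as printed
REFERENCE_PROFILES = [
    ComponentProfile(
        component_id=1,
        size=133,
        label_fractions={"BclA": 87 / 133, "MBacA": 46 / 133},
        majority_label="BclA",
        in_clade_c_fraction=1.0,
        monophyletic_in_tree=True,
    ),
    ComponentProfile(
        component_id=2,
        size=1,
        label_fractions={"ExsE": 1.0},
        majority_label="ExsE",
        in_clade_c_fraction=0.0,
        monophyletic_in_tree=True,
    ),
    ComponentProfile(
        component_id=4,
        size=1,
        label_fractions={"BclA": 1.0},
        majority_label="BclA",
        in_clade_c_fraction=0.0,
        monophyletic_in_tree=True,
    ),
    ComponentProfile(
        component_id=5,
        size=71,
        label_fractions={"BacA": 1.0},
        majority_label="BacA",
        in_clade_c_fraction=1.0,
        monophyletic_in_tree=True,
    ),
    ComponentProfile(
        component_id=6,
        size=44,
        label_fractions={"BclA": 33 / 44, "MBacA": 10 / 44, "other": 1 / 44},
        majority_label="BclA",
        in_clade_c_fraction=1.0,
        monophyletic_in_tree=True,
    ),
]

_ROWS = [
    # protein_id, species, hmm_label, clade, cluster
    ("P1_Polymorphum_gilvum_BacA", "Polymorphum gilvum", "BacA", "C", 5),
    ("P2_Synechococcus_elongatus_BclA", "Synechococcus elongatus", "BclA", "C", 6),
    ("P3_Cyanobacterium_aponinum_BclA", "Cyanobacterium aponinum", "BclA", "C", 6),
    ("P4_Basilea_psittacipulmonis_BclA", "Basilea psittacipulmonis", "MBacA", "C", 1),
    ("P5_Succinivibrio_dextrinosolvens_BclA", "Succinivibrio dextrinosolvens", "BclA", "C", 1),
    ("P6_Methylomusa_anaerophila_BclA", "Methylomusa anaerophila", "BclA", "C", 1),
    ("P7_Polaromonas_naphthalenivorans_BclA", "Polaromonas naphthalenivorans", "BclA", "C", 1),
    ("P8_Eikenella_exigua_BclA_like", "Eikenella exigua", "BclA", "B", 4),
    ("P9_Phyllobacterium_zundukense_ExsE", "Phyllobacterium zundukense", "ExsE", "A", 2),
]

# published final classifications (BclA-like and ExsE are not accept
# labels of the classifier: both map to excluded, with the clade rules
# recording why)
REFERENCE_FINALS = {
    "P1_Polymorphum_gilvum_BacA": "BacA",
    "P2_Synechococcus_elongatus_BclA": "BclA",
    "P3_Cyanobacterium_aponinum_BclA": "BclA",
    "P4_Basilea_psittacipulmonis_BclA": "BclA",
    "P5_Succinivibrio_dextrinosolvens_BclA": "BclA",
    "P6_Methylomusa_anaerophila_BclA": "BclA",
    "P7_Polaromonas_naphthalenivorans_BclA": "BclA",
    "P8_Eikenella_exigua_BclA_like": "excluded",  # published as BclA-like
    "P9_Phyllobacterium_zundukense_ExsE": "excluded",  # published as ExsE
}

_SIZE_OF = {p.component_id: p.size for p in REFERENCE_PROFILES}


def reference_evidence_rows() -> list[EvidenceRow]:
    """The nine published evidence tuples as EvidenceRow objects."""
    return [
        EvidenceRow(
            protein_id=pid,
            species_id=species,
            hmm_label=label,
            hmm_bits=float("nan"),
            component_id=cluster,
            component_size=_SIZE_OF.get(cluster, 1),
            clade=clade,
            long_branch=False,
        )
        for pid, species, label, clade, cluster in _ROWS
    ]
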