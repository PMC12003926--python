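"""Consensus classification of candidate transporter proteins.

Reconciles the three evidence streams — profile-HMM top-hit label, SSN
component membership, and phylogenetic clade — into a final call of
SbmA/BacA, BclA, or excluded, with a complete rule trace.

Rules fire in strict precedence, first match wins:

* R1  clade A -> excluded (outgroup families ExsE / Bradyrhizobium clade)
* R2  clade B -> excluded (the distinct BclA-like family)
* R3  component with BacA purity >= ``bacA_purity`` that is monophyletic
      in the tree (and large enough) -> SbmA/BacA
* R4  component with combined BclA + Mycobacterium-BacA purity >=
      ``bclA_purity`` and clade-C fraction >= ``clade_c_fraction_min``
      (and large enough) -> BclA
* R5  component with ExsE fraction >= 0.5 -> excluded
* R6  undersized component or long-branch leaf -> excluded
* R7  anything else -> excluded

The accept rules R3/R4 additionally require component size >=
``min_component_size``: small clusters and singletons are never accepted
regardless of label purity, mirroring the exclusion of the long-branch
three-protein cluster and singletons in the study this reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import ProteinRecord, SeedAlignment, SpeciesMeta
from .msa_phylo import (
    CladeAssignment,
    align_to_profile,
    assign_clades,
    distance_matrix,
    flag_long_branches,
    nj_tree,
    root_tree,
    trim_columns,
)
from .pairwise_ssn import SSN, ScoringScheme, all_vs_all, build_network
from .profile_hmm import (
    GumbelParams,
    HmmHit,
    ProfileHMM,
    annotate_top_hit,
    build_profile,
    calibrate,
    search_proteome,
)

HMM_LABELS = ("BacA", "BclA", "MBacA", "ExsE", "Brady", "other")
OUTGROUP_LABELS = ("ExsE", "Brady")
FINAL_LABELS = ("BacA", "BclA", "excluded")
EXCLUDED_REASONS = (
    "clade_A_outgroup",
    "clade_B_family",
    "exse_like_component",
    "small_or_singleton",
    "long_branch",
    "none",
)


@dataclass
class EvidenceRow:
    protein_id: str
    species_id: str
    hmm_label: str
    hmm_bits: float
    component_id: int
    component_size: int
    clade: str
    long_branch: bool


@dataclass
class ComponentProfile:
    component_id: int
    size: int
    label_fractions: dict[str, float]
    majority_label: str
    in_clade_c_fraction: float
    monophyletic_in_tree: bool


@dataclass
class RuleConfig:
    bacA_purity: float = 0.90
    bclA_purity: float = 0.75
    clade_c_fraction_min: float = 0.75
    min_component_size: int = 4

    def __post_init__(self) -> None:
        for name in ("bacA_purity", "bclA_purity", "clade_c_fraction_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")


@dataclass
class FinalCall:
    protein_id: str
    final_label: str
    excluded_reason: str
    rule_fired: str

    def __post_init__(self) -> None:
        if (self.final_label == "excluded") != (self.excluded_reason != "none"):
            raise ValueError("excluded_reason must be set iff excluded")


def assemble_evidence(
    hits: Sequence[HmmHit],
    ssn: SSN,
    clades: CladeAssignment,
    species_of: Mapping[str, str],
    universe: set[str] | None = None,
) -> list[EvidenceRow]:
    """Full join of the three evidence sources on protein_id.

    Proteins missing from any single source get sentinel values with a
    warning; a protein in the SSN that is absent from the FASTA universe
    is a hard error.
    """
    if universe is not None:
        stray = set(ssn.nodes) - universe
        if stray:
            raise ValueError(f"SSN proteins absent from input universe: {sorted(stray)[:5]}")
    hit_of = {h.protein_id: h for h in hits}
    ids = list(dict.fromkeys(list(hit_of) + list(ssn.nodes)))
    comp_sizes = [len(c) for c in ssn.components]
    rows = []
    n_missing = 0
    for pid in ids:
        h = hit_of.get(pid)
        if h is None:
            n_missing += 1
        cid = ssn.component_of.get(pid, -1)
        if cid < 0:
            n_missing += 1
        clade = clades.clade.get(pid)
        if clade is None:
            n_missing += 1
            clade = "unassigned"
        rows.append(
            EvidenceRow(
                protein_id=pid,
                species_id=species_of.get(pid, "unknown"),
                hmm_label=h.family_name if h else "other",
                hmm_bits=h.bit_score if h else float("nan"),
                component_id=cid,
                component_size=comp_sizes[cid] if cid >= 0 else 1,
                clade=clade,
                long_branch=clades.long_branch.get(pid, False),
            )
        )
    if n_missing:
        warnings.warn(f"{n_missing} evidence fields filled with sentinels", stacklevel=2)
    return rows


def _is_monophyletic(tree: dendropy.Tree, ids: set[str]) -> bool:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    present = ids & leaves
    if len(present) <= 1:
        return True
    # smallest node (from the seed) whose leaf set covers the ids
    best = None
    for node in tree.postorder_node_iter():
        under = {lf.taxon.label for lf in node.leaf_iter()}
        if present <= under and (best is None or len(under) < len(best)):
            best = under
    return best == present


def component_label_profile(
    rows: Sequence[EvidenceRow],
    tree: dendropy.Tree | None = None,
) -> list[ComponentProfile]:
    """Per-component label histogram, clade-C fraction and monophyly.

    Without a tree, monophyly is vacuously true (the worked-example path,
    where only the printed evidence tuples are available).
    """
    by_comp: dict[int, list[EvidenceRow]] = {}
    for r in rows:
        by_comp.setdefault(r.component_id, []).append(r)
    out = []
    for cid in sorted(by_comp):
        members = by_comp[cid]
        n = len(members)
        fracs = {lab: 0.0 for lab in HMM_LABELS}
        for r in members:
            fracs[r.hmm_label if r.hmm_label in fracs else "other"] += 1.0 / n
        majority = max(fracs, key=lambda lab: (fracs[lab], lab))
        in_c = sum(1 for r in members if r.clade == "C") / n
        mono = True if tree is None else _is_monophyletic(tree, {r.protein_id for r in members})
        out.append(ComponentProfile(cid, n, fracs, majority, in_c, mono))
    return out


def apply_rules(
    rows: Sequence[EvidenceRow],
    profiles: Sequence[ComponentProfile],
    cfg: RuleConfig | None = None,
) -> list[FinalCall]:
    """Apply the consensus rules in precedence order, one call per protein."""
    if cfg is None:
        cfg = RuleConfig()
    prof_of = {p.component_id: p for p in profiles}
    calls = []
    for r in rows:
        p = prof_of.get(r.component_id)
        size = p.size if p else r.component_size
        if r.clade == "A":
            calls.append(FinalCall(r.protein_id, "excluded", "clade_A_outgroup", "R1"))
            continue
        if r.clade == "B":
            calls.append(FinalCall(r.protein_id, "excluded", "clade_B_family", "R2"))
            continue
        if p is not None and size >= cfg.min_component_size:
            if p.label_fractions.get("BacA", 0.0) >= cfg.bacA_purity and p.monophyletic_in_tree:
                calls.append(FinalCall(r.protein_id, "BacA", "none", "R3"))
                continue
            bcl = p.label_fractions.get("BclA", 0.0) + p.label_fractions.get("MBacA", 0.0)
            if bcl >= cfg.bclA_purity and p.in_clade_c_fraction >= cfg.clade_c_fraction_min:
                calls.append(FinalCall(r.protein_id, "BclA", "none", "R4"))
                continue
        if p is not None and p.label_fractions.get("ExsE", 0.0) >= 0.5:
            calls.append(FinalCall(r.protein_id, "excluded", "exse_like_component", "R5"))
            continue
        if size < cfg.min_component_size:
            calls.append(FinalCall(r.protein_id, "excluded", "small_or_singleton", "R6"))
            continue
        if r.long_branch:
            calls.append(FinalCall(r.protein_id, "excluded", "long_branch", "R6"))
            continue
        calls.append(FinalCall(r.protein_id, "excluded", "small_or_singleton", "R7"))
    return calls


@dataclass
class FamilySeeds:
    """Seed alignments: one mining seed plus per-family annotation seeds."""

    mining: SeedAlignment
    families: dict[str, SeedAlignment]


@dataclass
class PipelineConfig:
    e_threshold: float = 1e-5
    ssn_threshold: float = 115.0
    occupancy_threshold: float = 0.5
    pseudocount: float = 1.0
    max_gap_fraction: float = 0.5
    long_branch_c: float = 5.0
    n_calib: int = 1000
    calib_len: int = 400
    prefilter_kmer: int | None = None
    rules: RuleConfig = field(default_factory=RuleConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    evidence: list[EvidenceRow]
    finals: list[FinalCall]
    hits: list[HmmHit]
    ssn: SSN | None
    tree: dendropy.Tree | None
    clades: CladeAssignment | None
    profiles: list[ComponentProfile]
    manifest: dict[str, object]


def classify_all(
    proteins: Sequence[ProteinRecord],
    species: Sequence[SpeciesMeta],
    seeds: FamilySeeds,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end pipeline: mine -> annotate -> SSN -> tree -> rules.

    ``proteins`` must carry species_id linkage; ``seeds`` provides the
    mining seed alignment (the SbmA/BacA-like family) and the per-family
    seeds used for top-hit annotation.
    """
    if cfg is None:
        cfg = PipelineConfig()
    manifest: dict[str, object] = {
        "n_proteins": len(proteins),
        "n_species": len(species),
        "e_threshold": cfg.e_threshold,
        "ssn_threshold": cfg.ssn_threshold,
        "occupancy_threshold": cfg.occupancy_threshold,
        "pseudocount": cfg.pseudocount,
        "max_gap_fraction": cfg.max_gap_fraction,
        "long_branch_c": cfg.long_branch_c,
        "n_calib": cfg.n_calib,
        "calib_len": cfg.calib_len,
        "rules": vars(cfg.rules).copy(),
        "seed": cfg.seed,
    }
    if not proteins:
        return PipelineResult([], [], [], None, None, None, [], manifest)

    species_of = {p.protein_id: p.species_id for p in proteins}
    universe = {p.protein_id for p in proteins}
    rec_of = {p.protein_id: p for p in proteins}

    # 1. mine candidates with the super-family model
    mining_hmm = build_profile(
        seeds.mining, cfg.occupancy_threshold, cfg.pseudocount, family_name="mining"
    )
    mining_gumbel = calibrate(mining_hmm, cfg.n_calib, cfg.calib_len, seed=cfg.seed)
    hits0 = search_proteome(
        mining_hmm, list(proteins), mining_gumbel, cfg.e_threshold, calib_len=cfg.calib_len
    )
    candidates = [rec_of[h.protein_id] for h in sorted(hits0, key=lambda h: h.protein_id)]
    manifest["n_candidates"] = len(candidates)
    if len(candidates) < 3:
        warnings.warn("fewer than 3 mined candidates; downstream stages skipped", stacklevel=2)
        return PipelineResult([], [], [], None, None, None, [], manifest)

    # 2. per-family top-hit annotation (argmax of bit scores; per-family
    # E-values are informational only, so no per-family calibration here)
    family_db = [
        build_profile(aln, cfg.occupancy_threshold, cfg.pseudocount, family_name=name)
        for name, aln in sorted(seeds.families.items())
    ]
    hits = [annotate_top_hit(rec, family_db) for rec in candidates]
    labels = {h.protein_id: h.family_name for h in hits}

    # 3. SSN over candidates
    pairs = all_vs_all(list(candidates), ScoringScheme(), cfg.prefilter_kmer)
    ssn = build_network(pairs, cfg.ssn_threshold, nodes=[c.protein_id for c in candidates])

    # 4. profile-guided MSA, NJ tree, rooting, clades
    msa = trim_columns(align_to_profile(mining_hmm, candidates), cfg.max_gap_fraction)
    dm = distance_matrix(msa)
    tree = nj_tree(dm)
    outgroup = {pid for pid, lab in labels.items() if lab in OUTGROUP_LABELS}
    if outgroup:
        tree = root_tree(tree, outgroup)
    else:
        warnings.warn("no outgroup-labeled candidates; tree left unrooted", stacklevel=2)
        tree.is_rooted = True
    clades = assign_clades(tree, ssn.components, labels, OUTGROUP_LABELS)
    clades.long_branch.update(flag_long_branches(tree, cfg.long_branch_c))

    # 5. evidence assembly and rules
    evidence = assemble_evidence(hits, ssn, clades, species_of, universe)
    profiles = component_label_profile(evidence, tree)
    finals = apply_rules(evidence, profiles, cfg.rules)
    manifest["n_final_bacA"] = sum(1 for f in finals if f.final_label == "BacA")
    manifest["n_final_bclA"] = sum(1 for f in finals if f.final_label == "BclA")
    return PipelineResult(evidence, finals, hits, ssn, tree, clades, profiles, manifest)


def replicate_ssn_study(
    fasta_path,
    threshold: float = 115.0,
    scheme: ScoringScheme | None = None,
):
    """All-vs-all SSN of a deposited candidate FASTA at a given threshold.

    Returns (ssn, component_stats) for an externally provided protein set
    (e.g. the deposited supplementary sequences of the original study).
    """
    from .io_formats import read_fasta
    from .pairwise_ssn import component_stats

    proteins = read_fasta(fasta_path)
    pairs = all_vs_all(proteins, scheme or ScoringScheme())
    ssn = build_network(pairs, threshold, nodes=[p.protein_id for p in proteins])
    return ssn, component_stats(ssn)
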