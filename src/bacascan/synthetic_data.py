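"""Synthetic benchmark generator with known family labels.

Generates the statistical structure the pipeline assumes, with no
external data: a birth-death species tree with nested taxonomy labels;
per-species family presence/absence produced by a continuous-time
gain/loss process with optional horizontal transfer (each family planted
at the root of its own species clade); family member sequences emitted
from per-family consensus profiles at a controlled divergence (the five
family consensuses are themselves related through a fixed guide topology
((ExsE,Brady),(BacA,(BclA,MBacA))) so the phylogenetic clades and the
SSN structure of the real analysis emerge); unrelated background decoys;
and a recovery scorer comparing final calls against the generated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .classify import FinalCall
from .io_formats import (
    AMINO_ACIDS,
    BACKGROUND,
    ProteinRecord,
    SeedAlignment,
    SpeciesMeta,
    write_fasta,
    write_newick,
    write_species_table,
    write_stockholm,
)

FAMILY_NAMES = ("BacA", "BclA", "MBacA", "ExsE", "Brady")

# anchor-clade priority: BclA gets the largest species clade so that it
# forms the largest SSN component, as in the data this emulates
ANCHOR_PRIORITY = ("BclA", "BacA", "MBacA", "ExsE", "Brady")

TRUTH_TO_FINAL = {
    "BacA": "BacA",
    "BclA": "BclA",
    "MBacA": "BclA",
    "ExsE": "excluded",
    "Brady": "excluded",
    "decoy": "excluded",
}

# substitution fractions along the fixed consensus guide topology
_GUIDE_BRANCHES = {
    "out": 0.15,
    "ing": 0.15,
    "ExsE": 0.35,
    "Brady": 0.35,
    "BacA": 0.35,
    "bb": 0.20,
    "BclA": 0.30,
    "MBacA": 0.30,
}


@dataclass
class FamilySpec:
    """Rates and root condition of one family's gain/loss/HGT process."""

    name: str
    gain_rate: float = 0.0
    loss_rate: float = 0.08
    hgt_rate: float = 0.02
    root_present: bool = False
    anchor_tips: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if min(self.gain_rate, self.loss_rate, self.hgt_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimConfig:
    n_species: int = 60
    birth_rate: float = 1.0
    death_rate: float = 0.0
    families: tuple[FamilySpec, ...] = tuple(FamilySpec(n) for n in FAMILY_NAMES)
    emission_divergence: float = 0.25
    n_decoys_per_species: int = 20
    decoy_length_mean: int = 400
    protein_length: int = 600
    consensus_weight: float = 0.0  # weight of the consensus residue when resampling
    seed_divergence: float = 0.05
    n_seed_rows: int = 8
    mining_rows_per_family: int = 2
    n_overlap_both: int = 2  # species of the BclA clade that also gain BacA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need n_species >= 3")
        if not 0 <= self.emission_divergence < 1:
            raise ValueError("emission_divergence must be in [0, 1)")


@dataclass
class TruthRecord:
    true_family: str
    species_id: str
    event_history: tuple[tuple[float, str], ...] = ()


@dataclass
class TruthTable:
    records: dict[str, TruthRecord]

    def family_of(self, protein_id: str) -> str:
        return self.records[protein_id].true_family


@dataclass
class FamilyProfile:
    """Consensus sequence plus the residue distribution used when mutating."""

    name: str
    consensus: np.ndarray  # int residue indices, length L
    consensus_weight: float = 0.0

    def resample(self, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw replacement residues for the given positions."""
        draws = rng.choice(20, size=pos.size, p=BACKGROUND)
        if self.consensus_weight > 0:
            keep = rng.random(pos.size) < self.consensus_weight
            draws[keep] = self.consensus[pos[keep]]
        return draws

    def emit(self, divergence: float, rng: np.random.Generator) -> str:
        seq = self.consensus.copy()
        hit = np.flatnonzero(rng.random(seq.size) < divergence)
        if hit.size:
            seq[hit] = self.resample(hit, rng)
        return "".join(AMINO_ACIDS[i] for i in seq)


@dataclass
class SyntheticBenchmark:
    proteins: list[ProteinRecord]
    species_table: list[SpeciesMeta]
    truth: TruthTable
    species_tree: dendropy.Tree
    mining_seed: SeedAlignment
    family_seeds: dict[str, SeedAlignment]
    profiles: dict[str, FamilyProfile]
    anchors: dict[str, frozenset[str]]


# ---------------------------------------------------------------------------
# species tree + taxonomy


def simulate_species_tree(
    n: int, birth: float, death: float, seed: int
) -> dendropy.Tree:
    """Birth-death tree conditioned on n extant tips, tips S0001..S{n}."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    import random as _random

    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n,
        rng=_random.Random(seed),
    )
    tree.seed_node.edge.length = None  # no stem branch
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:04d}"
    return tree


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def assign_taxonomy(tree: dendropy.Tree) -> list[SpeciesMeta]:
    """Nested taxonomy from clade membership at three depth cuts.

    Phylum/class/order are the lineages crossing 25/50/75% of the maximum
    root-to-tip depth; genus is the species itself (one representative
    genome per genus).
    """
    depth = _node_depths(tree)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    max_depth = max(depth[lf] for lf in leaves)
    cuts = [0.25 * max_depth, 0.5 * max_depth, 0.75 * max_depth]
    prefixes = ["P", "C", "O"]
    group_ids: list[dict[str, str]] = []
    for cut, prefix in zip(cuts, prefixes):
        seen: dict[int, str] = {}
        labels: dict[str, str] = {}
        for lf in leaves:
            node = lf
            while node.parent_node is not None and depth[node.parent_node] > cut:
                node = node.parent_node
            key = id(node)
            if key not in seen:
                seen[key] = f"{prefix}{len(seen) + 1:02d}"
            labels[lf.taxon.label] = seen[key]
        group_ids.append(labels)
    return [
        SpeciesMeta(
            species_id=lf.taxon.label,
            genus=f"G_{lf.taxon.label}",
            phylum=group_ids[0][lf.taxon.label],
            class_=group_ids[1][lf.taxon.label],
            order=group_ids[2][lf.taxon.label],
        )
        for lf in leaves
    ]


def pick_family_anchors(
    tree: dendropy.Tree, n_families: int = 5, min_size: int = 5
) -> list[frozenset[str]]:
    """Disjoint species groups hosting the families, largest first.

    Prefers true clades of the species tree (sizes capped near n/4 so no
    family swallows the tree and some species host no family at all); if
    the topology does not offer enough disjoint clades, remaining tips
    are grouped into contiguous (preorder) blocks.
    """
    n = sum(1 for _ in tree.leaf_node_iter())
    max_size = max(n // 4, min_size)
    clades = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if min_size <= len(tips) <= max_size:
            clades.append(tips)
    clades.sort(key=lambda s: (-len(s), sorted(s)[0]))
    chosen: list[frozenset[str]] = []
    used: set[str] = set()
    for tips in clades:
        if len(chosen) == n_families:
            break
        if tips & used:
            continue
        chosen.append(tips)
        used |= tips
    if len(chosen) < n_families:
        rest = [
            lf.taxon.label
            for lf in tree.preorder_node_iter()
            if lf.is_leaf() and lf.taxon.label not in used
        ]
        chosen.sort(key=lambda s: (-len(s), sorted(s)[0]))
        # if the leftover pool is too small, return the smallest chosen
        # clades to it so every family still gets >= 2 species
        while chosen and len(rest) < 2 * (n_families - len(chosen)):
            rest.extend(sorted(chosen.pop()))
        missing = n_families - len(chosen)
        if len(rest) < 2 * missing:
            raise ValueError("cannot place all families on disjoint species groups")
        base, extra = divmod(len(rest), missing)
        for i in range(missing):
            size = base + (1 if i < extra else 0)
            chosen.append(frozenset(rest[:size]))
            rest = rest[size:]
    chosen.sort(key=lambda s: (-len(s), sorted(s)[0]))
    return chosen[:n_families]


# ---------------------------------------------------------------------------
# gene content: global Gillespie over the tree timeline


def simulate_gene_content(
    tree: dendropy.Tree,
    families: Sequence[FamilySpec],
    seed: int,
) -> tuple[dict[tuple[str, str], bool], dict[str, list[tuple[float, str, str]]]]:
    """Continuous-time gain/loss with contemporaneous-donor HGT.

    Returns per-(species, family) presence and the per-family event list
    (time, event type, lineage label).  HGT copies a present family from
    a uniformly chosen other lineage alive at the event time; a planted
    gain is recorded where a family's anchor clade begins.
    """
    depth = _node_depths(tree)
    rng_root = np.random.SeedSequence(seed)
    presence: dict[tuple[str, str], bool] = {}
    all_events: dict[str, list[tuple[float, str, str]]] = {}

    def lineage_label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        tips = sorted(lf.taxon.label for lf in node.leaf_iter())
        return f"mrca({tips[0]},{tips[-1]})"

    for fam, child_ss in zip(families, rng_root.spawn(len(families))):
        rng = np.random.default_rng(child_ss)
        events: list[tuple[float, str, str]] = []
        anchor_node = None
        anchor_tip_starts: set[str] = set()
        if fam.anchor_tips:
            taxa = [tree.taxon_namespace.get_taxon(t) for t in sorted(fam.anchor_tips)]
            mrca = tree.mrca(taxa=[t for t in taxa if t is not None])
            mrca_tips = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
            if mrca_tips == fam.anchor_tips:
                anchor_node = mrca
            else:  # non-clade anchor: plant on each terminal branch instead
                anchor_tip_starts = set(fam.anchor_tips)

        # active branches (insertion-ordered dict keeps draws deterministic);
        # children of the seed node start at time 0 with the root state
        import heapq

        active: dict[dendropy.Node, bool] = {}
        heap: list[tuple[float, int, dendropy.Node]] = []
        counter = 0

        def spawn(node: dendropy.Node, state: bool, t: float) -> None:
            nonlocal counter
            if node is anchor_node or (
                node.is_leaf() and node.taxon.label in anchor_tip_starts
            ):
                if not state:
                    events.append((t, "planted_gain", lineage_label(node)))
                state = True
            active[node] = state
            heapq.heappush(heap, (depth[node], counter, node))
            counter += 1

        for child in tree.seed_node.child_nodes():
            spawn(child, fam.root_present, 0.0)
        t = 0.0
        while heap:
            t_next = heap[0][0]
            # Gillespie within [t, t_next) over the active branches
            while True:
                branches = list(active)
                rates = np.array(
                    [
                        (fam.loss_rate if active[b] else fam.gain_rate) + fam.hgt_rate
                        for b in branches
                    ]
                )
                total = float(rates.sum())
                if total <= 0.0:
                    break
                dt = rng.exponential(1.0 / total)
                if t + dt >= t_next:
                    break
                t += dt
                b = branches[int(rng.choice(len(branches), p=rates / total))]
                own = fam.loss_rate if active[b] else fam.gain_rate
                is_own = (own + fam.hgt_rate) > 0 and rng.random() < own / (own + fam.hgt_rate)
                if is_own:
                    if active[b]:
                        active[b] = False
                        events.append((t, "loss", lineage_label(b)))
                    else:
                        active[b] = True
                        events.append((t, "gain", lineage_label(b)))
                else:
                    donors = [d for d in branches if d is not b]
                    if donors:
                        d = donors[int(rng.integers(len(donors)))]
                        if active[d] and not active[b]:
                            active[b] = True
                            events.append((t, "hgt", lineage_label(b)))
            # process every branch end at t_next (zero-length children included)
            t = t_next
            while heap and heap[0][0] <= t_next + 1e-12:
                _, _, node = heapq.heappop(heap)
                state = active.pop(node)
                if node.is_leaf():
                    presence[(node.taxon.label, fam.name)] = state
                else:
                    for child in node.child_nodes():
                        spawn(child, state, t_next)
        all_events[fam.name] = events
    return presence, all_events


# ---------------------------------------------------------------------------
# sequences


def _mutate(seq: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute an expected fraction of positions to a different residue."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < fraction)
    for i in hit:
        new = rng.choice(20, p=BACKGROUND)
        while new == out[i]:
            new = rng.choice(20, p=BACKGROUND)
        out[i] = new
    return out


def family_consensus_profiles(
    length: int, seed: int, consensus_weight: float = 0.0
) -> dict[str, FamilyProfile]:
    """Five related consensus sequences along the fixed guide topology."""
    rng = np.random.default_rng(seed)
    anc = rng.choice(20, size=length, p=BACKGROUND)
    out = _mutate(anc, _GUIDE_BRANCHES["out"], rng)
    ing = _mutate(anc, _GUIDE_BRANCHES["ing"], rng)
    bb = _mutate(ing, _GUIDE_BRANCHES["bb"], rng)
    cons = {
        "ExsE": _mutate(out, _GUIDE_BRANCHES["ExsE"], rng),
        "Brady": _mutate(out, _GUIDE_BRANCHES["Brady"], rng),
        "BacA": _mutate(ing, _GUIDE_BRANCHES["BacA"], rng),
        "BclA": _mutate(bb, _GUIDE_BRANCHES["BclA"], rng),
        "MBacA": _mutate(bb, _GUIDE_BRANCHES["MBacA"], rng),
    }
    return {
        name: FamilyProfile(name, seq, consensus_weight) for name, seq in cons.items()
    }


def emit_family_sequences(
    presence: Mapping[tuple[str, str], bool],
    profiles: Mapping[str, FamilyProfile],
    emission_divergence: float,
    seed: int,
    events: Mapping[str, list[tuple[float, str, str]]] | None = None,
) -> tuple[list[ProteinRecord], TruthTable]:
    """One member sequence per present (species, family) pair."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict[str, TruthRecord] = {}
    for (species_id, fam_name), present in sorted(presence.items()):
        if not present:
            continue
        prof = profiles[fam_name]
        pid = f"{fam_name}_{species_id}"
        seq = prof.emit(emission_divergence, rng)
        records.append(
            ProteinRecord(pid, seq, species_id=species_id, description=f"synthetic {fam_name}")
        )
        hist: tuple[tuple[float, str], ...] = ()
        if events is not None:  # family-level history (time, event type)
            hist = tuple((t, ev) for (t, ev, _lin) in events.get(fam_name, []))
        truth[pid] = TruthRecord(fam_name, species_id, hist)
    return records, TruthTable(truth)


def make_decoys(
    n: int,
    length_mean: int,
    background: np.ndarray | None = None,
    seed: int = 0,
    id_prefix: str = "decoy",
) -> list[ProteinRecord]:
    """I.i.d. background-emitted sequences with geometric lengths."""
    if n < 0:
        raise ValueError("n must be >= 0")
    bg = BACKGROUND if background is None else background
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = max(30, int(rng.geometric(1.0 / length_mean)))
        seq = "".join(AMINO_ACIDS[j] for j in rng.choice(20, size=L, p=bg))
        out.append(ProteinRecord(f"{id_prefix}{i + 1:05d}", seq, description="synthetic decoy"))
    return out


def _seed_alignment(
    profiles: Mapping[str, FamilyProfile],
    members: Sequence[tuple[str, int]],
    divergence: float,
    rng: np.random.Generator,
) -> SeedAlignment:
    names, rows = [], []
    for fam, idx in members:
        names.append(f"{fam}_seed{idx}")
        rows.append(profiles[fam].emit(divergence, rng))
    return SeedAlignment(names, rows)


def generate_benchmark(cfg: SimConfig, out_dir: str | Path | None = None) -> SyntheticBenchmark:
    """Compose the simulators into a full benchmark; pure in (cfg, seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_content, s_emit, s_decoy, s_prof, s_seeds = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]
    tree = simulate_species_tree(cfg.n_species, cfg.birth_rate, cfg.death_rate, s_tree)
    species_table = assign_taxonomy(tree)
    n_fam = len(cfg.families)
    min_anchor = max(2, min(5, cfg.n_species // (n_fam + 1)))
    anchors_list = pick_family_anchors(tree, n_fam, min_size=min_anchor)
    # keep the first (BclA) anchor clearly the largest so the BclA cluster
    # tends to be the biggest SSN component, as in the emulated data
    if len(anchors_list) > 1:
        n0 = len(anchors_list[0])
        cap = max(n0 - 4, round(0.75 * n0), 2)
        anchors_list = [anchors_list[0]] + [
            frozenset(sorted(tips)[:cap]) if len(tips) > cap else tips
            for tips in anchors_list[1:]
        ]
    anchors: dict[str, frozenset[str]] = {}
    families = []
    by_name = {f.name: f for f in cfg.families}
    for fam_name, tips in zip(ANCHOR_PRIORITY, anchors_list):
        if fam_name not in by_name:
            continue
        spec = by_name[fam_name]
        anchors[fam_name] = tips
        families.append(
            FamilySpec(
                spec.name, spec.gain_rate, spec.loss_rate, spec.hgt_rate,
                spec.root_present, anchor_tips=tips,
            )
        )
    for f in cfg.families:  # families without anchor priority keep their spec
        if f.name not in anchors:
            families.append(f)

    presence, events = simulate_gene_content(tree, families, s_content)

    # configurable overlap: a few BclA-clade species also carry BacA
    if cfg.n_overlap_both > 0 and "BclA" in anchors:
        carriers = sorted(
            sp for sp in anchors["BclA"] if presence.get((sp, "BclA"), False)
        )
        for sp in carriers[: cfg.n_overlap_both]:
            if not presence.get((sp, "BacA"), False):
                presence[(sp, "BacA")] = True
                events.setdefault("BacA", []).append((float("nan"), "planted_overlap", sp))

    profiles = family_consensus_profiles(cfg.protein_length, s_prof, cfg.consensus_weight)
    members, truth = emit_family_sequences(
        presence, profiles, cfg.emission_divergence, s_emit, events
    )

    proteins = list(members)
    rng_decoy = np.random.default_rng(s_decoy)
    for sp in sorted(s.species_id for s in species_table):
        decoys = make_decoys(
            cfg.n_decoys_per_species,
            cfg.decoy_length_mean,
            seed=int(rng_decoy.integers(2**31)),
            id_prefix=f"decoy_{sp}_",
        )
        for d in decoys:
            d.species_id = sp
            truth.records[d.protein_id] = TruthRecord("decoy", sp)
        proteins.extend(decoys)

    rng_seeds = np.random.default_rng(s_seeds)
    mining_members = [
        (fam, i) for fam in FAMILY_NAMES for i in range(1, cfg.mining_rows_per_family + 1)
    ]
    mining_seed = _seed_alignment(profiles, mining_members, cfg.seed_divergence, rng_seeds)
    family_seeds = {
        fam: _seed_alignment(
            profiles,
            [(fam, i) for i in range(1, cfg.n_seed_rows + 1)],
            cfg.seed_divergence,
            rng_seeds,
        )
        for fam in FAMILY_NAMES
    }

    bench = SyntheticBenchmark(
        proteins, species_table, truth, tree, mining_seed, family_seeds, profiles, anchors
    )
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _write_benchmark(bench: SyntheticBenchmark, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list[ProteinRecord]] = {}
    for rec in bench.proteins:
        by_species.setdefault(rec.species_id, []).append(rec)
    fasta_dir = out_dir / "proteomes"
    fasta_dir.mkdir(exist_ok=True)
    for sp in sorted(by_species):
        write_fasta(by_species[sp], fasta_dir / f"{sp}.faa")
    write_species_table(bench.species_table, out_dir / "species.tsv")
    write_newick(bench.species_tree, out_dir / "species_tree.nwk")
    write_stockholm(bench.mining_seed, out_dir / "mining_seed.sto")
    for fam, seed in bench.family_seeds.items():
        write_stockholm(seed, out_dir / f"seed_{fam}.sto")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("protein_id\ttrue_family\tspecies_id\n")
        for pid in sorted(bench.truth.records):
            tr = bench.truth.records[pid]
            fh.write(f"{pid}\t{tr.true_family}\t{tr.species_id}\n")


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryScore:
    per_class: dict[str, tuple[float, float, float]]  # label -> (P, R, F1)
    macro_f1: float
    component_purity: float  # NaN when no component map given
    n_proteins: int


def score_recovery(
    finals: Sequence[FinalCall],
    truth: TruthTable,
    component_of: Mapping[str, int] | None = None,
) -> RecoveryScore:
    """Confusion-matrix metrics of final labels against generated truth.

    Truth families map to expected finals (BacA->BacA; BclA, MBacA->BclA;
    ExsE, Brady, decoy->excluded); proteins absent from ``finals`` count
    as excluded.  A class absent from both truth and predictions scores
    a vacuous 1.0.
    """
    pred = {}
    for f in finals:
        if f.protein_id not in truth.records:
            raise ValueError(f"unknown protein id {f.protein_id!r} in finals")
        pred[f.protein_id] = f.final_label
    per_class = {}
    f1s = []
    for label in ("BacA", "BclA", "excluded"):
        tp = fp = fn = 0
        for pid, rec in truth.records.items():
            expected = TRUTH_TO_FINAL[rec.true_family]
            got = pred.get(pid, "excluded")
            if got == label and expected == label:
                tp += 1
            elif got == label:
                fp += 1
            elif expected == label:
                fn += 1
        if tp + fp + fn == 0:
            p = r = f1 = 1.0
        else:
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
        per_class[label] = (p, r, f1)
        f1s.append(f1)
    purity = float("nan")
    if component_of is not None:
        sizes = 0
        weighted = 0.0
        comps: dict[int, list[str]] = {}
        for pid, cid in component_of.items():
            comps.setdefault(cid, []).append(pid)
        for members in comps.values():
            fams = [truth.records[p].true_family for p in members if p in truth.records]
            if not fams:
                continue
            top = max(fams.count(f) for f in set(fams))
            weighted += top
            sizes += len(fams)
        purity = weighted / sizes if sizes else float("nan")
    return RecoveryScore(per_class, float(np.mean(f1s)), purity, len(truth.records))
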