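"""Readers and writers for the on-disk formats shared by the pipeline.

Covers multi-FASTA proteomes, Stockholm seed alignments, the species
metadata table, Newick trees, SSN edge lists, evidence tables and a
minimal iTOL-style binary presence annotation.  All writers are
deterministic: identical in-memory inputs produce byte-identical files
(fixed column order, floats at six significant digits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

# Canonical amino-acid alphabet; X is the catch-all 21st symbol and scores
# zero against everything downstream.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
X_INDEX = 20
ALPHABET = AMINO_ACIDS + "X"

# Non-canonical residue codes are folded into X at parse time (single
# normalization point for the whole pipeline).
_AMBIGUOUS = set("BZUOJ")

# Robinson & Robinson amino-acid background frequencies (order as AMINO_ACIDS).
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856,
        0.07377, 0.02199, 0.05142, 0.05744, 0.09019,
        0.02243, 0.04487, 0.05203, 0.04264, 0.05129,
        0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def fmt6(x: float) -> str:
    """Format a float to six significant digits (writer convention)."""
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return f"{x:.6g}"


@dataclass
class ProteinRecord:
    """A single protein with optional species linkage.

    Species linkage is by an explicit mapping (``species_id``), never by
    FASTA-header parsing; protein IDs are treated as opaque strings.
    """

    protein_id: str
    sequence: str
    species_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass
class SpeciesMeta:
    """Taxonomic metadata for one species (one representative per genus)."""

    species_id: str
    genus: str
    phylum: str
    class_: str
    order: str


@dataclass
class SeedAlignment:
    """An aligned set of seed sequences used to build a profile HMM."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if self.n_rows < 2:
            raise ValueError("seed alignment needs at least 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged seed alignment: row widths {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


def normalize_sequence(seq: str, protein_id: str = "?") -> str:
    """Uppercase, strip ``*`` stops, fold non-canonical residues to X."""
    out = []
    for ch in seq.upper():
        if ch == "*":
            continue
        if ch in _AMBIGUOUS:
            ch = "X"
        if ch not in AA_INDEX and ch != "X":
            raise ValueError(f"invalid residue {ch!r} in protein {protein_id!r}")
        out.append(ch)
    return "".join(out)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a normalized sequence as int8 indices (X -> 20)."""
    arr = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch == "X":
            arr[i] = X_INDEX
        else:
            try:
                arr[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"invalid residue {ch!r}") from None
    return arr


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-FASTA file into :class:`ProteinRecord` objects.

    Order is preserved; sequences are uppercased with ``*`` stripped;
    duplicate IDs and empty records are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.protein_id
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_stockholm_seed(path: str | Path) -> SeedAlignment:
    """Read a Stockholm 1.0 seed alignment; gap symbols normalized to '-'."""
    aln = AlignIO.read(str(path), "stockholm")
    names, rows = [], []
    for rec in aln:
        row = str(rec.seq).upper().replace(".", "-")
        row = "".join("X" if c in _AMBIGUOUS else c for c in row)
        names.append(rec.id)
        rows.append(row)
    return SeedAlignment(names, rows)


def write_stockholm(seed: SeedAlignment, path: str | Path) -> None:
    name_w = max(len(n) for n in seed.names)
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, row in zip(seed.names, seed.rows):
            fh.write(f"{name:<{name_w}}  {row}\n")
        fh.write("//\n")


_SPECIES_COLUMNS = ("species_id", "genus", "phylum", "class", "order")


def read_species_table(path: str | Path) -> list[SpeciesMeta]:
    """Read the TSV species table (species_id/genus/phylum/class/order)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated species_id: {sorted(set(dup))}")
    out = []
    for _, row in df.iterrows():
        vals = [row[c] if isinstance(row[c], str) and row[c] else "unknown" for c in _SPECIES_COLUMNS]
        out.append(SpeciesMeta(*vals))
    return out


def write_species_table(species: Iterable[SpeciesMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SPECIES_COLUMNS) + "\n")
        for sp in species:
            fh.write("\t".join([sp.species_id, sp.genus, sp.phylum, sp.class_, sp.order]) + "\n")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree in Newick format (round-trip safe with read_newick)."""
    s = tree.as_string(schema="newick", suppress_rooting=True, real_value_format_specifier=".6g")
    with open(path, "w") as fh:
        fh.write(s)


def read_newick(path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def write_edge_list(ssn, path: str | Path) -> None:
    """Write SSN edges as TSV: id1, id2, raw, bits, alignment score, %id."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\traw_score\tbit_score\talignment_score\tpct_identity\n")
        for e in sorted(ssn.edges, key=lambda e: (e.id1, e.id2)):
            fh.write(
                f"{e.id1}\t{e.id2}\t{e.raw_score:d}\t{fmt6(e.bit_score)}\t"
                f"{fmt6(e.alignment_score)}\t{fmt6(e.pct_identity)}\n"
            )


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id1\t"):
            raise ValueError(f"unexpected edge-list header in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], parts[1], float(parts[4])))
    return out


_EVIDENCE_COLUMNS = (
    "protein_id",
    "species_id",
    "hmm_label",
    "hmm_bits",
    "component_id",
    "component_size",
    "clade",
    "long_branch",
)


def write_evidence_table(rows: Sequence, path: str | Path) -> None:
    """Write per-protein evidence rows as a TSV with fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.protein_id}\t{r.species_id}\t{r.hmm_label}\t{fmt6(r.hmm_bits)}\t"
                f"{r.component_id}\t{r.component_size}\t{r.clade}\t{int(r.long_branch)}\n"
            )


def write_final_calls(finals: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfinal_label\texcluded_reason\trule_fired\n")
        for f in finals:
            fh.write(f"{f.protein_id}\t{f.final_label}\t{f.excluded_reason}\t{f.rule_fired}\n")


def write_itol_presence(pa, path: str | Path) -> None:
    """Write a minimal iTOL binary-dataset annotation of BacA/BclA presence.

    One row per species: label then presence of SbmA/BacA and BclA coded
    1/0 (red/blue rings in an iTOL binary dataset).
    """
    with open(path, "w") as fh:
        fh.write("DATASET_BINARY\nSEPARATOR TAB\nDATASET_LABEL\ttransporters\n")
        fh.write("FIELD_SHAPES\t2\t2\nFIELD_LABELS\tSbmA/BacA\tBclA\n")
        fh.write("FIELD_COLORS\t#d62728\t#1f77b4\nDATA\n")
        for sp in sorted(pa.per_species):
            n_bacA, n_bclA = pa.per_species[sp]
            fh.write(f"{sp}\t{int(n_bacA > 0)}\t{int(n_bclA > 0)}\n")
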