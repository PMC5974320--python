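"""Readers and writers for the pipeline's external data formats.

Tables are TSV (UTF-8, '.' decimal, lines starting with ``#`` ignored);
segment tables are wide-form with a ``<segment>_r<replicate>`` column
grammar (e.g. ``A_r1 .. E_r3``). UTRs arrive as FASTA; motifs as MEME
minimal format or a one-motif-per-line IUPAC list. RNA alphabets are
normalized to DNA (U -> T) on ingest; coordinates are 0-based, half-open,
forward strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif_scan import Motif, parse_consensus

log = logging.getLogger(__name__)

RNA_SEGMENTS = ["A", "B", "C", "D", "E"]
PROTEIN_SEGMENTS = ["A", "B", "C", "D"]

_COL_RE = re.compile(r"^([A-Za-z]+)_r(\d+)$")


def segments_for(molecule_kind: str) -> list[str]:
    """Canonical animal-pole-first segment labels for a molecule kind."""
    if molecule_kind == "rna":
        return RNA_SEGMENTS
    if molecule_kind == "protein":
        return PROTEIN_SEGMENTS
    raise ValueError(f"unknown molecule kind {molecule_kind!r}")


def _parse_columns(columns: list[str], allowed: list[str]) -> tuple[list[str], list[int]]:
    segs, reps = [], []
    for col in columns:
        m = _COL_RE.match(col)
        if not m:
            raise ValueError(f"column {col!r} does not match '<segment>_r<replicate>'")
        seg, rep = m.group(1).upper(), int(m.group(2))
        if seg not in allowed:
            raise ValueError(f"unknown segment label {seg!r} (expected one of {allowed})")
        if seg not in segs:
            segs.append(seg)
        if rep not in reps:
            reps.append(rep)
    segs = [s for s in allowed if s in segs]   # canonical animal-first order
    return segs, sorted(reps)


@dataclass
class SegmentTable:
    """Gene x (segment, replicate) table of counts or intensities.

    ``data`` is indexed by gene id with ``<segment>_r<replicate>`` columns;
    segments are ordered animal pole first. Values are non-negative reals;
    missing cells are NaN.
    """

    data: pd.DataFrame
    segments: list[str]
    replicates: list[int]
    molecule_kind: str

    def __post_init__(self) -> None:
        if self.molecule_kind not in ("rna", "protein"):
            raise ValueError(f"unknown molecule kind {self.molecule_kind!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("segment table contains negative values")
        expected = [f"{s}_r{r}" for s in self.segments for r in self.replicates]
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.data = self.data[expected]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def values3d(self) -> np.ndarray:
        """(n_genes, n_segments, n_replicates) array; missing cells are NaN."""
        arr = self.data.to_numpy(dtype=float)
        return arr.reshape(len(self.data), len(self.segments), len(self.replicates))

    def replicate_frame(self, rep: int) -> pd.DataFrame:
        """Gene x segment values for one replicate."""
        cols = [f"{s}_r{rep}" for s in self.segments]
        frame = self.data[cols].copy()
        frame.columns = self.segments
        return frame

    def copy_with(self, data: pd.DataFrame) -> "SegmentTable":
        return SegmentTable(data, list(self.segments), list(self.replicates),
                            self.molecule_kind)


def read_segment_table(path: str | Path, molecule_kind: str) -> SegmentTable:
    allowed = segments_for(molecule_kind)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    segs, reps = _parse_columns(list(df.columns), allowed)
    # normalize column names to upper-case segment labels
    df.columns = [
        f"{m.group(1).upper()}_r{int(m.group(2))}"
        for m in (_COL_RE.match(c) for c in df.columns)
    ]
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.warning("%s: %d missing cells flagged as NaN", path, n_missing)
    return SegmentTable(df, segs, reps, molecule_kind)


def write_segment_table(table: SegmentTable, path: str | Path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.data.rename_axis("gene").to_csv(fh, sep="\t")


@dataclass
class CqTable:
    """qPCR quantification cycles for anchor genes.

    ``data``: anchors x ``<segment>_r<replicate>`` Cq values. ``efficiency``
    maps each anchor to its amplification efficiency in (1, 2]; relative
    quantity is efficiency**(-Cq).
    """

    data: pd.DataFrame
    segments: list[str]
    replicates: list[int]
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for anchor in self.data.index:
            eff = self.efficiency.setdefault(anchor, 2.0)
            if not 1.0 < eff <= 2.0:
                raise ValueError(f"anchor {anchor!r}: efficiency {eff} not in (1, 2]")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite Cq value")

    @property
    def anchor_ids(self) -> list[str]:
        return list(self.data.index)

    def replicate_frame(self, rep: int) -> pd.DataFrame:
        cols = [f"{s}_r{rep}" for s in self.segments]
        frame = self.data[cols].copy()
        frame.columns = self.segments
        return frame


def read_cq_table(path: str | Path, molecule_kind: str = "rna",
                  efficiency: dict[str, float] | None = None) -> CqTable:
    allowed = segments_for(molecule_kind)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    segs, reps = _parse_columns(list(df.columns), allowed)
    return CqTable(df, segs, reps, dict(efficiency or {}))


def write_cq_table(cq: CqTable, path: str | Path) -> None:
    cq.data.rename_axis("anchor").to_csv(path, sep="\t")


@dataclass
class UtrSet:
    """3'UTR sequences (DNA alphabet after U->T) with optional category labels."""

    records: dict[str, str]
    category_map: dict[str, str] | None = None

    def subset(self, gene_ids) -> dict[str, str]:
        return {g: self.records[g] for g in gene_ids if g in self.records}

    def by_category(self) -> dict[str, dict[str, str]]:
        if self.category_map is None:
            raise ValueError("no category map attached to this UTR set")
        out: dict[str, dict[str, str]] = {}
        for g, seq in self.records.items():
            cat = self.category_map.get(g)
            if cat is not None:
                out.setdefault(cat, {})[g] = seq
        return out


_VALID_UTR = re.compile(r"^[ACGT]+$")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def read_fasta_utrs(path: str | Path, category_map: dict[str, str] | None = None) -> UtrSet:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in records:
            raise ValueError(f"duplicate FASTA record {gene_id!r}")
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty sequence for {gene_id!r}")
        if not _VALID_UTR.match(seq):
            raise ValueError(f"non-nucleotide character in {gene_id!r} "
                             "(ambiguity codes are not allowed in UTRs)")
        records[gene_id] = seq
    return UtrSet(records, category_map)


def write_fasta_utrs(utrs: UtrSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id, seq in utrs.records.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class MotifFile:
    """A set of motif definitions read from one file."""

    motifs: list[Motif]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [m.id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate motif ids in motif file")


def read_meme_minimal(path: str | Path, source_tag: str = "") -> MotifFile:
    """Parse MEME minimal motif format, or fall back to an IUPAC list.

    The IUPAC dialect is one motif per line: either ``<consensus>`` or
    ``<id><whitespace><consensus>``; ``#`` comments and blank lines ignored.
    """
    text = Path(path).read_text(encoding="utf-8")
    if "MEME version" in text:
        return MotifFile(_parse_meme(text), source_tag or "meme-minimal")
    motifs = []
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            motifs.append(Motif(id=f"m{i + 1}", consensus=parts[0],
                                source_tag=source_tag or "iupac-list"))
        else:
            motifs.append(Motif(id=parts[0], consensus=parts[1],
                                source_tag=source_tag or "iupac-list"))
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return MotifFile(motifs, source_tag or "iupac-list")


def _parse_meme(text: str) -> list[Motif]:
    lines = text.splitlines()
    alphabet = "ACGT"
    motifs: list[Motif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = normalize_sequence(line.split("=", 1)[1].strip())
            if alphabet != "ACGT":
                raise ValueError(f"unsupported alphabet {alphabet!r}")
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {name!r}: no letter-probability matrix")
                j += 1
            if j >= len(lines):
                raise ValueError(f"motif {name!r}: no letter-probability matrix")
            m = re.search(r"w\s*=\s*(\d+)", lines[j])
            rows = []
            j += 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) == 4 and all(_is_float(p) for p in parts):
                    rows.append([float(p) for p in parts])
                    j += 1
                else:
                    break
            if m and int(m.group(1)) != len(rows):
                raise ValueError(f"motif {name!r}: declared width {m.group(1)} "
                                 f"!= {len(rows)} matrix rows")
            pwm = np.array(rows)
            if pwm.size == 0:
                raise ValueError(f"motif {name!r}: empty matrix")
            bad = np.abs(pwm.sum(axis=1) - 1.0) > 1e-6
            if bad.any():
                row = int(np.argmax(bad))
                raise ValueError(
                    f"motif {name!r}: probability row {row} sums to "
                    f"{pwm[row].sum():.6g}, not 1")
            motifs.append(Motif(id=name, pwm=pwm, source_tag="meme-minimal"))
            i = j
            continue
        i += 1
    if not motifs:
        raise ValueError("no MOTIF blocks found")
    return motifs


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_meme_minimal(motifs: list[Motif], path: str | Path,
                       background: np.ndarray | None = None) -> None:
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*bg))
        for m in motifs:
            pwm = m.to_pwm()
            fh.write(f"MOTIF {m.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.shape[0]}\n")
            for row in pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``gene<TAB>category`` -> mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("category map needs at least two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_category_map(labels: dict[str, str], path: str | Path) -> None:
    pd.Series(labels, name="category").rename_axis("gene").to_csv(path, sep="\t")
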