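"""Tiling-array probe design.

A resequencing tiling design places, at every tiled genomic position, one
21-mer perfect-match (PM) probe centered on that position plus up to three
mismatch (MM) probes obtained by substituting the central (11th) base of
the PM sequence.  Probes alternate between the forward and reverse strand
along the genome.  Positions are 1-based; the "position" of a probe is the
genomic coordinate of its central base.

The design is held column-wise (positions, strands, central substitutions
as numpy arrays) and probe sequences are materialised on demand from the
genome, which keeps genome-scale designs (tens of millions of probes)
cheap to build and count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._codes import BASES, CENTER, PROBE_LENGTH, decode, encode

logger = logging.getLogger(__name__)

SUPPORTED_RESOLUTIONS = (1, 3, 5, 7, 9, 11, 13)
MM_MODES = ("all_three", "complementary_only", "none")

# the three alternative base codes for each central base code, ascending
_ALT_TABLE = np.array([[b for b in range(4) if b != c] for c in range(4)],
                      dtype=np.int8)

_OFFSETS = np.arange(-CENTER, CENTER + 1)


@dataclass(frozen=True)
class Probe:
    """One 21-mer probe, identified by the genome position of its center."""

    probe_id: str
    position: int
    strand: str  # '+' or '-'
    kind: str  # 'PM' or 'MM'
    central_alt: str | None  # probe-space substituted base; None iff PM
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError("probe sequence must be exactly 21 bases")
        if (self.kind == "PM") != (self.central_alt is None):
            raise ValueError("central_alt must be set iff the probe is MM")


class TilingDesign:
    """Column-wise container for a tiling probe design.

    Parameters
    ----------
    genome_code : uint8 array of base codes for the reference genome
    centers : 1-based central positions, one entry per probe, sorted
    strands : 0 (forward) / 1 (reverse) per probe
    alts : probe-space central substitution code per probe, -1 for PM
    """

    def __init__(self, genome_code: np.ndarray, genome_id: str,
                 circular: bool, resolution: int,
                 centers: np.ndarray, strands: np.ndarray, alts: np.ndarray):
        self.genome_code = np.asarray(genome_code, dtype=np.uint8)
        self.genome_id = genome_id
        self.circular = bool(circular)
        self.resolution = int(resolution)
        self.centers = np.asarray(centers, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=np.uint8)
        self.alts = np.asarray(alts, dtype=np.int8)
        if not (len(self.centers) == len(self.strands) == len(self.alts)):
            raise ValueError("probe column arrays must have equal length")

    # ------------------------------------------------------------------
    @property
    def genome_length(self) -> int:
        return len(self.genome_code)

    @property
    def genome_sequence(self) -> str:
        return decode(self.genome_code)

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def n_pm(self) -> int:
        return int((self.alts < 0).sum())

    # ------------------------------------------------------------------
    def _window_codes(self, idx: np.ndarray) -> np.ndarray:
        """Forward-strand genomic 21-mers around the selected centers."""
        pos0 = self.centers[idx] - 1
        mat = pos0[:, None] + _OFFSETS[None, :]
        if self.circular:
            mat = mat % self.genome_length
        return self.genome_code[mat]

    def pm_codes(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Probe-space PM (reference) sequences as an (n, 21) code array."""
        if idx is None:
            idx = np.arange(len(self))
        idx = np.atleast_1d(np.asarray(idx))
        win = self._window_codes(idx)
        rev = self.strands[idx] == 1
        win[rev] = 3 - win[rev][:, ::-1]
        return win

    def probe_codes(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Actual probe sequences (MM central substitution applied)."""
        if idx is None:
            idx = np.arange(len(self))
        idx = np.atleast_1d(np.asarray(idx))
        win = self.pm_codes(idx)
        alts = self.alts[idx]
        mm = alts >= 0
        win[mm, CENTER] = alts[mm].astype(np.uint8)
        return win

    def central_pm_code(self, idx: np.ndarray) -> np.ndarray:
        """Probe-space reference central base code for the selected probes."""
        idx = np.atleast_1d(np.asarray(idx))
        g = self.genome_code[self.centers[idx] - 1].astype(np.int8)
        return np.where(self.strands[idx] == 1, 3 - g, g).astype(np.int8)

    # ------------------------------------------------------------------
    def probe_id(self, i: int) -> str:
        strand = "F" if self.strands[i] == 0 else "R"
        if self.alts[i] < 0:
            return f"{self.centers[i]}{strand}:PM"
        return f"{self.centers[i]}{strand}:MM{BASES[self.alts[i]]}"

    def probe_ids(self) -> list[str]:
        return [self.probe_id(i) for i in range(len(self))]

    def __getitem__(self, i: int) -> Probe:
        seq = decode(self.probe_codes(np.array([i]))[0])
        alt = None if self.alts[i] < 0 else BASES[self.alts[i]]
        return Probe(
            probe_id=self.probe_id(i),
            position=int(self.centers[i]),
            strand="+" if self.strands[i] == 0 else "-",
            kind="PM" if alt is None else "MM",
            central_alt=alt,
            sequence=seq,
        )

    def __iter__(self) -> Iterator[Probe]:
        for i in range(len(self)):
            yield self[i]

    # ------------------------------------------------------------------
    def covering_indices(self, position: int) -> np.ndarray:
        """Indices of probes whose 21-base span contains ``position``."""
        L = self.genome_length
        if not (1 <= position <= L):
            raise ValueError(f"position {position} outside genome of {L} bp")
        lo, hi = position - CENTER, position + CENTER
        if self.circular:
            if lo < 1:
                segs = [(lo + L, L), (1, hi)]
            elif hi > L:
                segs = [(lo, L), (1, hi - L)]
            else:
                segs = [(lo, hi)]
        else:
            segs = [(max(lo, 1), min(hi, L))]
        parts = []
        for a, b in segs:
            start = np.searchsorted(self.centers, a, side="left")
            stop = np.searchsorted(self.centers, b, side="right")
            parts.append(np.arange(start, stop))
        return np.sort(np.concatenate(parts))

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        seqs = self.probe_codes()
        return pd.DataFrame({
            "probe_id": self.probe_ids(),
            "position": self.centers,
            "strand": np.where(self.strands == 0, "+", "-"),
            "kind": np.where(self.alts < 0, "PM", "MM"),
            "central_alt": [
                "." if a < 0 else BASES[a] for a in self.alts],
            "sequence": ["".join(row) for row in
                         np.array(list(BASES))[seqs]],
            "array": ((self.centers - 1) // self.resolution) % 3 + 1,
        })

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#genome_id={self.genome_id}\n")
            fh.write(f"#genome_length={self.genome_length}\n")
            fh.write(f"#circular={'true' if self.circular else 'false'}\n")
            fh.write(f"#resolution={self.resolution}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _coerce_genome(genome) -> tuple[np.ndarray, str]:
    """Accept a str, Bio.Seq or SeqRecord and return (codes, id)."""
    genome_id = "genome"
    if hasattr(genome, "seq"):  # SeqRecord
        genome_id = getattr(genome, "id", genome_id) or genome_id
        genome = str(genome.seq)
    else:
        genome = str(genome)
    return encode(genome.upper()), genome_id


def _valid_window_mask(valid: np.ndarray, circular: bool) -> np.ndarray:
    """Per-position flag: is the centered 21-bp window all ACGT?"""
    v = valid.astype(np.int32)
    if circular:
        v3 = np.concatenate([v[-CENTER:], v, v[:CENTER]])
        cs = np.concatenate([[0], np.cumsum(v3)])
        return (cs[PROBE_LENGTH:] - cs[:-PROBE_LENGTH]) == PROBE_LENGTH
    cs = np.concatenate([[0], np.cumsum(v)])
    out = np.zeros(len(v), dtype=bool)
    ok = cs[PROBE_LENGTH:] - cs[:-PROBE_LENGTH] == PROBE_LENGTH
    out[CENTER:len(v) - CENTER] = ok
    return out


def _expand(genome_code, centers, strands, mm_mode):
    """Expand PM centers into per-probe columns (PM first, MM by base)."""
    g = genome_code[centers - 1].astype(np.int8)
    central = np.where(strands == 1, 3 - g, g).astype(np.int8)
    if mm_mode == "none":
        return centers, strands, np.full(len(centers), -1, dtype=np.int8)
    if mm_mode == "all_three":
        alts = _ALT_TABLE[central]  # (M, 3), ascending
        n_mm = 3
    elif mm_mode == "complementary_only":
        alts = (3 - central)[:, None]
        n_mm = 1
    else:
        raise ValueError(f"unknown mm_mode {mm_mode!r}")
    k = 1 + n_mm
    out_centers = np.repeat(centers, k)
    out_strands = np.repeat(strands, k)
    out_alts = np.concatenate(
        [np.full((len(centers), 1), -1, dtype=np.int8), alts], axis=1
    ).ravel()
    return out_centers, out_strands, out_alts


def build_tiling_design(genome, resolution: int = 1, circular: bool = True,
                        mm_mode: str = "all_three",
                        genome_id: str | None = None) -> TilingDesign:
    """Tile a genome at the given resolution with PM and MM probes.

    Strand alternates with the tiled index (even index forward, odd
    reverse).  Tiled positions whose 21-bp window contains a non-ACGT
    character are skipped with a logged warning.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if mm_mode not in MM_MODES:
        raise ValueError(f"mm_mode must be one of {MM_MODES}")
    code, auto_id = _coerce_genome(genome)
    genome_id = genome_id or auto_id
    L = len(code)
    if L < PROBE_LENGTH:
        raise ValueError("genome must be at least 21 bp")

    centers = np.arange(1, L + 1, resolution, dtype=np.int64)
    if not circular:
        centers = centers[(centers >= CENTER + 1) & (centers <= L - CENTER)]
    tiled_index = (centers - 1) // resolution
    strands = (tiled_index % 2).astype(np.uint8)

    ok = _valid_window_mask(code <= 3, circular)[centers - 1]
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "skipped %d tiled positions with non-ACGT bases in their "
            "21-bp window", n_skipped)
        centers, strands = centers[ok], strands[ok]

    c, s, a = _expand(code, centers, strands, mm_mode)
    return TilingDesign(code, genome_id, circular, resolution, c, s, a)


def reduce_resolution(design: TilingDesign, r: int,
                      mm_mode: str = "all_three") -> TilingDesign:
    """Thin a full 1-bp design down to an r-bp tiling sub-design.

    ``complementary_only`` additionally keeps, per PM probe, only the MM
    probe whose central base is the Watson-Crick complement of the PM
    central base (the subset some downstream methods can use).
    """
    if design.resolution != 1:
        raise ValueError("reduce_resolution expects a 1-bp design")
    if r not in SUPPORTED_RESOLUTIONS:
        raise ValueError(f"resolution must be one of {SUPPORTED_RESOLUTIONS}")
    keep = (design.centers - 1) % r == 0
    if mm_mode == "complementary_only":
        comp = 3 - design.central_pm_code(np.arange(len(design)))
        keep &= (design.alts < 0) | (design.alts == comp)
    elif mm_mode != "all_three":
        raise ValueError("mm_mode must be all_three or complementary_only")
    return TilingDesign(design.genome_code, design.genome_id, design.circular,
                        r, design.centers[keep], design.strands[keep],
                        design.alts[keep])


def probes_covering(design: TilingDesign, position: int) -> list[Probe]:
    """All probes whose 21-base genomic span includes ``position``.

    Returned in deterministic order: by position, PM before MM, then MM
    central base A<C<G<T.
    """
    return [design[int(i)] for i in design.covering_indices(position)]


def read_design_tsv(path) -> TilingDesign:
    """Read a design TSV written by :meth:`TilingDesign.to_tsv`.

    The reference genome is reconstructed from the overlapping PM probe
    sequences, so the TSV is self-contained.
    """
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"central_alt": str})
    L = int(meta["genome_length"])
    circular = meta.get("circular", "true") == "true"
    resolution = int(meta.get("resolution", 1))
    genome_id = meta.get("genome_id", "genome")

    code = np.full(L, 255, dtype=np.uint8)
    pm = df[df["kind"] == "PM"]
    for pos, strand, seq in zip(pm["position"], pm["strand"], pm["sequence"]):
        s = encode(seq)
        if strand == "-":
            s = 3 - s[::-1]
        mat = (pos - 1 + _OFFSETS)
        if circular:
            mat = mat % L
        code[mat] = s

    alts = np.array([-1 if a == "." else BASES.index(a)
                     for a in df["central_alt"]], dtype=np.int8)
    design = TilingDesign(
        code, genome_id, circular, resolution,
        df["position"].to_numpy(np.int64),
        np.where(df["strand"].to_numpy() == "+", 0, 1).astype(np.uint8),
        alts,
    )
    # sanity: regenerated sequences must agree with the file
    regen = design.probe_codes(np.arange(min(len(design), 50)))
    for i, row in enumerate(regen):
        if decode(row) != df["sequence"].iloc[i]:
            raise ValueError("design TSV is inconsistent with its own "
                             "PM-derived genome reconstruction")
    return design
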