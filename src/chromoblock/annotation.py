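"""Map genomic interval tracks onto the 100-kbp bead representation.

A chromosome is discretised into fixed-size bins (beads).  Each bead gets a
forest/prairie class by base-pair majority vote, a lamina-association flag
called at the level of whole F/P domains, and a TAD-boundary flag.  Centromere
bins are removed and the chain re-indexed so the polymer stays contiguous.

All genomic coordinates are 0-based half-open; strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicTrack",
    "BeadAnnotation",
    "bin_to_beads",
    "call_lads",
    "mark_tad_boundaries",
    "drop_centromere",
    "read_bed",
    "write_bed",
    "read_beads_tsv",
    "write_beads_tsv",
    "domain_runs",
]

DEFAULT_BIN_BP = 100_000

# Labels recognised for the two sequence classes (CGI-rich / CGI-poor).
FOREST_LABELS = frozenset({"F", "forest", "Forest", "FOREST"})
PRAIRIE_LABELS = frozenset({"P", "prairie", "Prairie", "PRAIRIE"})


@dataclass(frozen=True)
class GenomicTrack:
    """A set of labelled intervals on one chromosome.

    Intervals are (start_bp, end_bp, label) with 0-based half-open
    coordinates.  ``normalized()`` sorts the intervals and checks the
    invariants (non-negative, start < end, non-overlapping).
    """

    chromosome_name: str
    intervals: tuple[tuple[int, int, str], ...]

    def __init__(self, chromosome_name: str,
                 intervals: Iterable[tuple[int, int, str]]):
        object.__setattr__(self, "chromosome_name", chromosome_name)
        object.__setattr__(self, "intervals", tuple(
            (int(s), int(e), str(lab)) for s, e, lab in intervals))

    def normalized(self) -> "GenomicTrack":
        ivs = sorted(self.intervals)
        for s, e, _ in ivs:
            if s < 0:
                raise ValueError(f"negative coordinate {s}")
            if s >= e:
                raise ValueError(f"empty or inverted interval [{s}, {e})")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping intervals at {s1} < {e0} "
                    f"on {self.chromosome_name}")
        return GenomicTrack(self.chromosome_name, ivs)

    @property
    def extent_bp(self) -> int:
        """End coordinate of the right-most interval (0 if empty)."""
        return max((e for _, e, _ in self.intervals), default=0)


@dataclass(frozen=True)
class BeadAnnotation:
    """One coarse-grained bead: a 100-kbp genomic bin.

    ``bin_index`` counts retained bins consecutively along the chain
    (centromere bins removed); ``source_bp_start`` remembers where the bin
    came from on the original sequence.
    """

    chain_id: int
    bin_index: int
    domain_class: str  # "F" or "P"
    is_lad: bool
    is_tad_boundary: bool
    source_bp_start: int

    def __post_init__(self):
        if self.domain_class not in ("F", "P"):
            raise ValueError(f"domain_class must be F or P, "
                             f"got {self.domain_class!r}")


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def bin_to_beads(fp_track: GenomicTrack, bin_bp: int = DEFAULT_BIN_BP,
                 chain_id: int = 0, tie_class: str = "P",
                 min_tail_fraction: float = 0.5) -> list[BeadAnnotation]:
    """Assign F/P classes to fixed-size bins by base-pair majority.

    A bin is F (P) iff strictly more than 50% of its base pairs carry the
    forest (prairie) label; a bin winning neither vote — ties and poorly
    covered bins — falls back to ``tie_class`` (default P, the CGI-poor
    background).  A trailing partial bin is kept if it spans at least
    ``min_tail_fraction`` of a full bin.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    track = fp_track.normalized()
    if not track.intervals:
        raise ValueError("empty forest/prairie track")
    extent = track.extent_bp
    n_full, tail = divmod(extent, bin_bp)
    n_bins = n_full + (1 if tail >= min_tail_fraction * bin_bp else 0)
    if n_bins == 0:
        raise ValueError("track shorter than half a bin")

    beads = []
    for b in range(n_bins):
        lo = b * bin_bp
        hi = min(lo + bin_bp, extent) if b == n_full else lo + bin_bp
        size = hi - lo
        f_bp = sum(_overlap(lo, hi, s, e) for s, e, lab in track.intervals
                   if lab in FOREST_LABELS)
        p_bp = sum(_overlap(lo, hi, s, e) for s, e, lab in track.intervals
                   if lab in PRAIRIE_LABELS)
        if f_bp * 2 > size:
            cls = "F"
        elif p_bp * 2 > size:
            cls = "P"
        else:
            cls = tie_class
        beads.append(BeadAnnotation(chain_id=chain_id, bin_index=b,
                                    domain_class=cls, is_lad=False,
                                    is_tad_boundary=False,
                                    source_bp_start=lo))
    return beads


def domain_runs(beads: Sequence[BeadAnnotation]) -> list[tuple[int, int]]:
    """Maximal runs of same-class beads within one chain, as [start, stop)
    index ranges into ``beads``."""
    runs = []
    start = 0
    for i in range(1, len(beads) + 1):
        if (i == len(beads)
                or beads[i].domain_class != beads[start].domain_class
                or beads[i].chain_id != beads[start].chain_id):
            runs.append((start, i))
            start = i
    return runs


def call_lads(beads: Sequence[BeadAnnotation],
              lad_signal_track: GenomicTrack,
              bin_bp: int = DEFAULT_BIN_BP,
              bead_signal_fraction: float = 0.5) -> list[BeadAnnotation]:
    """Call lamina-associated domains at the whole-domain level.

    A bead carries signal if lamina-association intervals overlap more than
    ``bead_signal_fraction`` of its bin.  A domain (maximal same-class run)
    becomes a LAD — every bead flagged — iff strictly more than half of its
    beads carry signal.
    """
    track = lad_signal_track.normalized()
    has_signal = []
    for bead in beads:
        lo = bead.source_bp_start
        hi = lo + bin_bp
        cov = sum(_overlap(lo, hi, s, e) for s, e, _ in track.intervals)
        has_signal.append(cov > bead_signal_fraction * bin_bp)

    out = [replace(b, is_lad=False) for b in beads]
    for start, stop in domain_runs(beads):
        n_sig = sum(has_signal[start:stop])
        if n_sig * 2 > (stop - start):
            for i in range(start, stop):
                out[i] = replace(out[i], is_lad=True)
    return out


def mark_tad_boundaries(beads: Sequence[BeadAnnotation],
                        boundary_track: GenomicTrack,
                        bin_bp: int = DEFAULT_BIN_BP) -> list[BeadAnnotation]:
    """Flag a bead iff at least one TAD-boundary position falls in its bin.

    Point boundaries are intervals of any length; the interval start is the
    boundary position (half-open, so bp 0 lands in bead 0).
    """
    track = boundary_track.normalized()
    positions = [s for s, _, _ in track.intervals]
    out = []
    for bead in beads:
        lo = bead.source_bp_start
        hi = lo + bin_bp
        flag = any(lo <= p < hi for p in positions)
        out.append(replace(bead, is_tad_boundary=flag))
    return out


def drop_centromere(beads: Sequence[BeadAnnotation],
                    centromere_track: GenomicTrack,
                    bin_bp: int = DEFAULT_BIN_BP) -> list[BeadAnnotation]:
    """Remove beads whose bin midpoint lies inside the centromere and
    re-index the survivors consecutively (the chain is bonded across the
    gap).  An empty centromere track is the identity."""
    track = centromere_track.normalized()
    if not track.intervals:
        return list(beads)
    out = []
    for bead in beads:
        mid = bead.source_bp_start + bin_bp // 2
        inside = any(s <= mid < e for s, e, _ in track.intervals)
        if not inside:
            out.append(bead)
    if not out:
        raise ValueError("centromere covers the whole chromosome")
    return [replace(b, bin_index=i) for i, b in enumerate(out)]


# ---------------------------------------------------------------------------
# I/O: BED3/BED4 tracks and the bead-annotation TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, default_label: str = "") -> GenomicTrack:
    """Read a BED3/BED4 file as a GenomicTrack (first chromosome only if the
    file mixes several; a mixed file raises)."""
    rows = []
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if chrom is None:
                chrom = parts[0]
            elif parts[0] != chrom:
                raise ValueError(
                    f"multiple chromosomes in {path}: {chrom}, {parts[0]}")
            label = parts[3] if len(parts) > 3 else default_label
            rows.append((int(parts[1]), int(parts[2]), label))
    return GenomicTrack(chrom or "chr", rows)


def write_bed(track: GenomicTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, lab in track.intervals:
            if lab:
                fh.write(f"{track.chromosome_name}\t{s}\t{e}\t{lab}\n")
            else:
                fh.write(f"{track.chromosome_name}\t{s}\t{e}\n")


def beads_to_fp_track(beads: Sequence[BeadAnnotation],
                      chromosome_name: str = "chr",
                      bin_bp: int = DEFAULT_BIN_BP) -> GenomicTrack:
    """Serialise bead classes back to a BED-style F/P track (one interval
    per contiguous same-class run of bins, in source coordinates)."""
    ivs = []
    for start, stop in domain_runs(beads):
        lo = beads[start].source_bp_start
        hi = beads[stop - 1].source_bp_start + bin_bp
        ivs.append((lo, hi, beads[start].domain_class))
    return GenomicTrack(chromosome_name, ivs)


_TSV_COLUMNS = ["chain", "bin", "bp_start", "class", "is_lad",
                "is_tad_boundary"]


def write_beads_tsv(beads: Sequence[BeadAnnotation],
                    path: str | Path) -> None:
    df = pd.DataFrame({
        "chain": [b.chain_id for b in beads],
        "bin": [b.bin_index for b in beads],
        "bp_start": [b.source_bp_start for b in beads],
        "class": [b.domain_class for b in beads],
        "is_lad": [int(b.is_lad) for b in beads],
        "is_tad_boundary": [int(b.is_tad_boundary) for b in beads],
    })
    df.to_csv(path, sep="\t", index=False)


def read_beads_tsv(path: str | Path) -> list[BeadAnnotation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bead TSV missing columns: {sorted(missing)}")
    return [
        BeadAnnotation(chain_id=int(r.chain), bin_index=int(r.bin),
                       domain_class=str(r["class"]),
                       is_lad=bool(r.is_lad),
                       is_tad_boundary=bool(r.is_tad_boundary),
                       source_bp_start=int(r.bp_start))
        for _, r in df.iterrows()
    ]
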