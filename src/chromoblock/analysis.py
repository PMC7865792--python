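"""Observables: contact maps, P(N) scaling, RDFs, spectra, chain statistics.

All statistics pool frames from every supplied trajectory (replicas weighted
per frame).  Two beads are in contact when their center-to-center distance is
strictly below 2.5 σ0; the contact map entry is the fraction of pooled frames
in contact, giving Hi-C-like ensemble contact probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels as K
from .annotation import BeadAnnotation
from .engine import Trajectory
from .model import Container

__all__ = [
    "ContactMap",
    "PsCurve",
    "RegimeFit",
    "RadialProfile",
    "SpectrumSummary",
    "contact_map",
    "ps_curve",
    "fit_power_law",
    "fp_ratio_curve",
    "rdf",
    "windowed_fft",
    "interchain_stats",
    "align_experimental",
]

CONTACT_THRESHOLD = 2.5   # σ0
BIN_KBP = 100             # genomic size of one bead


@dataclass
class ContactMap:
    matrix: np.ndarray                  # (n, n) frequencies in [0, 1]
    beads: list[BeadAnnotation]
    n_frames: int

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]

    def chain_ids(self) -> np.ndarray:
        return np.array([b.chain_id for b in self.beads])

    def classes(self) -> np.ndarray:
        return np.array([b.domain_class for b in self.beads])


@dataclass
class PsCurve:
    """Mean contact probability vs genomic separation (kbps)."""

    N_kbps: np.ndarray
    P: np.ndarray
    class_filter: str = "all"   # all | FF | PP

    def at(self, n_kbps: float) -> float:
        """P at the nearest grid point to ``n_kbps``."""
        k = int(np.argmin(np.abs(self.N_kbps - n_kbps)))
        return float(self.P[k])


@dataclass
class RegimeFit:
    window_kbps: tuple[float, float]
    alpha: float
    intercept: float
    residual: float
    n_points: int


@dataclass
class RadialProfile:
    """Ensemble-averaged number density of F and P beads in 200 equal-width
    radial shells, indexed by normalized radius r/R (shell midpoints)."""

    r_over_R: np.ndarray
    density_F: np.ndarray
    density_P: np.ndarray
    shell_volumes: np.ndarray


@dataclass
class SpectrumSummary:
    frequencies: np.ndarray          # cycles per bin
    amplitude_F: np.ndarray | None   # mean spectrum of F-majority windows
    amplitude_P: np.ndarray | None
    n_windows_F: int = 0
    n_windows_P: int = 0


# ---------------------------------------------------------------------------

def contact_map(trajectories: Trajectory | Sequence[Trajectory],
                threshold: float = CONTACT_THRESHOLD) -> ContactMap:
    """Ensemble contact frequencies over all frames of all trajectories."""
    trajs = ([trajectories] if isinstance(trajectories, Trajectory)
             else list(trajectories))
    if not trajs or sum(t.n_frames for t in trajs) == 0:
        raise ValueError("no frames to analyse")
    beads = trajs[0].beads
    n = trajs[0].n_beads
    counts = np.zeros((n, n), dtype=np.int64)
    total = 0
    for t in trajs:
        counts += K.contact_counts(np.ascontiguousarray(t.frames), threshold)
        total += t.n_frames
    matrix = counts / total
    np.fill_diagonal(matrix, 1.0)
    return ContactMap(matrix=matrix, beads=list(beads), n_frames=total)


def ps_curve(cmap: ContactMap, class_filter: str = "all",
             chain: int | None = None) -> PsCurve:
    """P(N): mean contact probability over same-chain pairs at each
    separation N (the diagonal N = 0 is excluded).

    ``class_filter`` FF (PP) keeps only pairs whose two beads are both
    F (P).  Multi-chain maps pool same-chain pairs across chains unless a
    single ``chain`` is requested.
    """
    if class_filter not in ("all", "FF", "PP"):
        raise ValueError("class_filter must be all, FF or PP")
    chains = cmap.chain_ids()
    classes = cmap.classes()
    n = cmap.n_beads
    keep_chain = np.ones(n, dtype=bool) if chain is None else chains == chain

    sums: dict[int, float] = {}
    cnts: dict[int, int] = {}
    for cid in np.unique(chains[keep_chain]):
        idx = np.where((chains == cid) & keep_chain)[0]
        cls = classes[idx]
        sub = cmap.matrix[np.ix_(idx, idx)]
        m = len(idx)
        for sep in range(1, m):
            i = np.arange(m - sep)
            j = i + sep
            vals = sub[i, j]
            if class_filter == "FF":
                mask = (cls[i] == "F") & (cls[j] == "F")
                vals = vals[mask]
            elif class_filter == "PP":
                mask = (cls[i] == "P") & (cls[j] == "P")
                vals = vals[mask]
            if vals.size:
                sums[sep] = sums.get(sep, 0.0) + float(vals.sum())
                cnts[sep] = cnts.get(sep, 0) + int(vals.size)
    seps = np.array(sorted(sums), dtype=float)
    P = np.array([sums[int(s)] / cnts[int(s)] for s in seps])
    return PsCurve(N_kbps=seps * BIN_KBP, P=P, class_filter=class_filter)


def fit_power_law(ps: PsCurve,
                  window_kbps: tuple[float, float]) -> RegimeFit:
    """Least-squares fit of log10 P vs log10 N inside the window;
    alpha = −slope.  Non-positive P points are dropped."""
    lo, hi = window_kbps
    mask = (ps.N_kbps >= lo) & (ps.N_kbps <= hi) & (ps.P > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive points in window [{lo}, {hi}] kbps, "
            f"have {int(mask.sum())}")
    x = np.log10(ps.N_kbps[mask])
    y = np.log10(ps.P[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return RegimeFit(window_kbps=(lo, hi), alpha=float(-slope),
                     intercept=float(intercept), residual=resid,
                     n_points=int(mask.sum()))

# Regime windows of the three-regime decay (kbps): TAD scale, intermediate
# fractal-globule-like scale, long range (comparison capped at 20 Mbps).
REGIME_WINDOWS = {
    "tad": (300.0, 700.0),
    "intermediate": (700.0, 7000.0),
    "long": (7000.0, 20000.0),
}


def fp_ratio_curve(ps_ff: PsCurve,
                   ps_pp: PsCurve) -> tuple[np.ndarray, np.ndarray]:
    """P_FF(N)/P_PP(N) on the shared N grid; P_PP = 0 points omitted."""
    common = np.intersect1d(ps_ff.N_kbps, ps_pp.N_kbps)
    if common.size == 0:
        raise ValueError("curves share no N grid points")
    pf = ps_ff.P[np.isin(ps_ff.N_kbps, common)]
    pp = ps_pp.P[np.isin(ps_pp.N_kbps, common)]
    ok = pp > 0
    return common[ok], pf[ok] / pp[ok]


def rdf(trajectories: Trajectory | Sequence[Trajectory],
        container: Container | None = None,
        n_shells: int = 200,
        beads: Sequence[BeadAnnotation] | None = None) -> RadialProfile:
    """F/P number density in equal-thickness radial shells, frame-averaged.

    A bead outside the container is an integrity violation and raises.
    """
    trajs = ([trajectories] if isinstance(trajectories, Trajectory)
             else list(trajectories))
    if container is None:
        container = trajs[0].container
    if beads is None:
        beads = trajs[0].beads
    R = container.radius
    edges = np.linspace(0.0, R, n_shells + 1)
    vols = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    classes = np.array([b.domain_class for b in beads])
    is_f = classes == "F"

    count_f = np.zeros(n_shells)
    count_p = np.zeros(n_shells)
    n_frames = 0
    for t in trajs:
        for f in range(t.n_frames):
            r = np.linalg.norm(t.frames[f], axis=1)
            if np.any(r > R):
                raise ValueError("bead outside container in frame "
                                 f"{f}: r_max = {r.max():.3f} > R = {R}")
            sh = np.minimum((r / R * n_shells).astype(int), n_shells - 1)
            count_f += np.bincount(sh[is_f], minlength=n_shells)
            count_p += np.bincount(sh[~is_f], minlength=n_shells)
            n_frames += 1
    mid = (edges[:-1] + edges[1:]) / 2.0 / R
    return RadialProfile(r_over_R=mid,
                         density_F=count_f / n_frames / vols,
                         density_P=count_p / n_frames / vols,
                         shell_volumes=vols)


def windowed_fft(cmap: ContactMap, diagonal_offset: int = 5,
                 window_beads: int = 20) -> SpectrumSummary:
    """Windowed Fourier analysis of the k-th contact-map diagonal.

    The diagonal vector map[i, i+k] is cut into non-overlapping windows of
    ``window_beads`` bins (2 Mbps at 100-kbp bins); each window is
    mean-subtracted and its amplitude spectrum taken; spectra are averaged
    separately over F-majority and P-majority windows (a window is F when
    strictly more than half of its underlying beads are F).
    """
    n = cmap.n_beads
    if n <= window_beads + diagonal_offset:
        raise ValueError("chain too short for the requested window")
    diag = np.array([cmap.matrix[i, i + diagonal_offset]
                     for i in range(n - diagonal_offset)])
    classes = cmap.classes()
    spectra = {"F": [], "P": []}
    for s in range(0, len(diag) - window_beads + 1, window_beads):
        w = diag[s:s + window_beads]
        cls_w = classes[s:s + window_beads]
        n_f = int(np.sum(cls_w == "F"))
        label = "F" if 2 * n_f > window_beads else "P"
        amp = np.abs(np.fft.rfft(w - w.mean()))
        spectra[label].append(amp)
    freqs = np.fft.rfftfreq(window_beads)
    return SpectrumSummary(
        frequencies=freqs,
        amplitude_F=(np.mean(spectra["F"], axis=0)
                     if spectra["F"] else None),
        amplitude_P=(np.mean(spectra["P"], axis=0)
                     if spectra["P"] else None),
        n_windows_F=len(spectra["F"]),
        n_windows_P=len(spectra["P"]),
    )


def interchain_stats(cmap: ContactMap,
                     long_range_kbps: float = 5000.0) -> dict:
    """Intra-chain long-range and inter-chain mean contact probabilities.

    intra[c]: mean over same-chain pairs separated by more than
    ``long_range_kbps``; inter[(a, b)]: mean over all bead pairs of chains
    a and b.
    """
    chains = cmap.chain_ids()
    uniq = np.unique(chains)
    if len(uniq) < 2:
        raise ValueError("interchain statistics need at least two chains")
    min_sep = int(long_range_kbps / BIN_KBP)
    intra = {}
    for cid in uniq:
        idx = np.where(chains == cid)[0]
        sub = cmap.matrix[np.ix_(idx, idx)]
        m = len(idx)
        vals = []
        for sep in range(min_sep + 1, m):
            i = np.arange(m - sep)
            vals.append(sub[i, i + sep])
        intra[int(cid)] = (float(np.concatenate(vals).mean())
                           if vals else float("nan"))
    inter = {}
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            ia = np.where(chains == uniq[a])[0]
            ib = np.where(chains == uniq[b])[0]
            inter[(int(uniq[a]), int(uniq[b]))] = float(
                cmap.matrix[np.ix_(ia, ib)].mean())
    return {"intra": intra, "inter": inter,
            "long_range_kbps": long_range_kbps}


def align_experimental(exp_curve: np.ndarray, sim: PsCurve,
                       anchor_kbps: float = 300.0) -> np.ndarray:
    """Rescale an external P(N) table (columns N_kbps, P) so its value at
    the anchor separation (nearest grid point) equals the simulated one.

    Returns a new (m, 2) array; the simulation curve is never rescaled.
    """
    exp_curve = np.asarray(exp_curve, dtype=float)
    if exp_curve.ndim != 2 or exp_curve.shape[1] != 2:
        raise ValueError("experimental curve must be a two-column table")
    k = int(np.argmin(np.abs(exp_curve[:, 0] - anchor_kbps)))
    p_exp = exp_curve[k, 1]
    if p_exp <= 0:
        raise ValueError("experimental P at the anchor must be positive")
    factor = sim.at(anchor_kbps) / p_exp
    out = exp_curve.copy()
    out[:, 1] *= factor
    return out
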