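"""Spectral preprocessing: calibration, baseline, alignment, PQN, bucketing.

Turns raw 1D spectra into an aligned, normalized, bucketed feature
matrix.  The pipeline order is fixed: calibrate -> baseline -> exclude
-> align -> PQN -> bucket.

* Calibration shifts each spectrum by an integer number of grid steps
  so the reference (TSP) singlet sits at 0.00 ppm.
* Baseline correction uses asymmetric least squares (AsLS): a smooth
  curve is fit with a second-difference penalty and asymmetric weights
  so that it hugs the spectrum from below, then subtracted.
* Alignment is a CluPA-style hierarchical segment procedure: the sample
  best correlated with the median spectrum is the reference; each other
  sample is shifted segment-by-segment (integer grid shifts, recursing
  on segment halves) to maximize correlation with the reference.
* PQN (probabilistic quotient normalization) removes per-sample
  dilution: after integral normalization, each sample is divided by the
  median of its pointwise quotients against a reference spectrum.
* Intelligent bucketing places bucket edges at local minima of the mean
  spectrum inside a target region (default 0.8-8.5 ppm) and integrates
  each bucket per sample; buckets failing a signal-to-noise threshold
  or intersecting excluded regions are dropped (but kept accessible for
  conservation checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

from .synth import Spectrum

__all__ = [
    "SpectraMatrix",
    "BucketTable",
    "calibrate_to_reference",
    "baseline_correct",
    "exclude_regions",
    "align_spectra",
    "pqn_normalize",
    "intelligent_bucket",
]

log = logging.getLogger("afnmr.preprocess")


@dataclass
class SpectraMatrix:
    """Samples x points intensity matrix on one shared ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str]
    groups: list[str]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensity rows must match the ppm axis length")
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for lo, hi in self.excluded_regions:
            if lo >= hi:
                raise ValueError(f"bad excluded region ({lo}, {hi})")

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectraMatrix":
        ppm = spectra[0].ppm
        for s in spectra[1:]:
            if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
                raise ValueError("spectra do not share a common ppm axis")
        return cls(
            ppm=ppm.copy(),
            intensities=np.vstack([s.intensity for s in spectra]),
            sample_ids=[s.sample_id for s in spectra],
            groups=[s.group for s in spectra],
        )

    def unexcluded_mask(self) -> np.ndarray:
        mask = np.ones(self.ppm.size, dtype=bool)
        for lo, hi in self.excluded_regions:
            mask &= ~((self.ppm >= lo) & (self.ppm < hi))
        return mask

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.ppm.copy(), self.intensities.copy(),
            list(self.sample_ids), list(self.groups),
            list(self.excluded_regions),
        )


@dataclass
class BucketTable:
    """Integrated bucket intensities.

    ``buckets`` are half-open ppm windows [lo, hi) sorted in descending
    ppm order (NMR convention); ``values`` is samples x buckets.  The
    buckets dropped by the S/N and exclusion filters are retained in
    ``dropped``/``dropped_values`` so that partition conservation can be
    verified.
    """

    buckets: list[tuple[float, float]]
    values: np.ndarray
    sample_ids: list[str]
    groups: list[str]
    dropped: list[tuple[float, float]] = field(default_factory=list)
    dropped_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket integrals must be finite")
        asc = sorted(self.buckets)
        for (lo1, hi1), (lo2, _hi2) in zip(asc, asc[1:]):
            if lo2 < hi1 - 1e-12:
                raise ValueError("buckets overlap")

    @property
    def labels(self) -> list[str]:
        return [f"{lo:.4f}-{hi:.4f}" for lo, hi in self.buckets]

    @property
    def centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.buckets])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_to_reference(
    spectrum: Spectrum, ref_ppm: float = 0.0, search_window: float = 0.2
) -> Spectrum:
    """Shift a spectrum so the dominant peak near ``ref_ppm`` sits at
    ``ref_ppm`` (integer grid-step shift; intensity values unchanged).

    Raises if no peak in the window exceeds 5x the window's median
    absolute intensity.
    """
    ppm, y = spectrum.ppm, spectrum.intensity
    mask = (ppm >= ref_ppm - search_window) & (ppm <= ref_ppm + search_window)
    if not mask.any():
        raise ValueError("search window outside the ppm axis")
    seg = y[mask]
    med = np.median(np.abs(seg))
    imax = np.argmax(seg)
    if seg[imax] <= 5.0 * med:
        raise ValueError(
            f"no reference peak above 5x median intensity near {ref_ppm} ppm"
        )
    peak_ppm = ppm[np.flatnonzero(mask)[imax]]
    dx = (ppm[-1] - ppm[0]) / (ppm.size - 1)
    steps = int(round((peak_ppm - ref_ppm) / dx))
    shifted = _shift_edge_fill(y, -steps)
    return Spectrum(ppm.copy(), shifted, spectrum.sample_id, spectrum.group)


def _shift_edge_fill(y: np.ndarray, steps: int) -> np.ndarray:
    """Shift a vector by ``steps`` grid points, filling with edge values."""
    if steps == 0:
        return y.copy()
    out = np.empty_like(y)
    if steps > 0:
        out[steps:] = y[:-steps]
        out[:steps] = y[0]
    else:
        out[:steps] = y[-steps:]
        out[steps:] = y[-1]
    return out


# ---------------------------------------------------------------------------
# Baseline correction (asymmetric least squares)
# ---------------------------------------------------------------------------

def _asls_baseline(y: np.ndarray, lam: float, p: float, niter: int = 10) -> np.ndarray:
    n = y.size
    # banded representation (upper form) of lam * D2'D2, D2 = second difference
    bands = np.zeros((3, n))
    bands[0, 2:] = 1.0  # second super-diagonal
    bands[1, 1] = bands[1, -1] = -2.0  # first super-diagonal
    bands[1, 2:-1] = -4.0
    bands[2] = 6.0  # main diagonal
    bands[2, 0] = bands[2, -1] = 1.0
    bands[2, 1] = bands[2, -2] = 5.0
    bands *= lam
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = bands.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(
    spectrum: Spectrum | SpectraMatrix,
    smoothness: float = 1e7,
    asymmetry: float = 1e-3,
) -> Spectrum | SpectraMatrix:
    """Subtract an AsLS-estimated slowly varying baseline.

    ``smoothness`` is the second-difference penalty weight (larger =
    stiffer baseline); ``asymmetry`` the weight given to points above
    the current baseline estimate.  Peak apex heights above the local
    baseline are preserved to within a few percent.
    """
    if isinstance(spectrum, SpectraMatrix):
        out = spectrum.copy()
        for i in range(out.intensities.shape[0]):
            row = out.intensities[i]
            if not np.all(np.isfinite(row)):
                raise ValueError(f"non-finite intensities in {out.sample_ids[i]}")
            out.intensities[i] = row - _asls_baseline(row, smoothness, asymmetry)
        return out
    y = spectrum.intensity
    if y.size < 256:
        raise ValueError("need at least 256 points for baseline estimation")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    z = _asls_baseline(y, smoothness, asymmetry)
    return Spectrum(spectrum.ppm.copy(), y - z, spectrum.sample_id, spectrum.group)


# ---------------------------------------------------------------------------
# Excluded regions
# ---------------------------------------------------------------------------

def exclude_regions(
    matrix: SpectraMatrix,
    regions: list[tuple[float, float]] = ((4.5, 5.0),),
) -> SpectraMatrix:
    """Mark ppm regions (e.g. residual water) to be ignored by
    normalization, bucketing and S/N estimation.  Overlapping regions
    are merged; intensities are left untouched."""
    out = matrix.copy()
    merged = _merge_intervals(list(out.excluded_regions) + [tuple(r) for r in regions])
    lo_ax, hi_ax = min(matrix.ppm[0], matrix.ppm[-1]), max(matrix.ppm[0], matrix.ppm[-1])
    for lo, hi in merged:
        if hi <= lo_ax or lo >= hi_ax:
            raise ValueError(f"excluded region ({lo}, {hi}) outside the ppm axis")
    out.excluded_regions = merged
    return out


def _merge_intervals(regions: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not regions:
        return []
    regions = sorted((float(lo), float(hi)) for lo, hi in regions)
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        plo, phi = merged[-1]
        if lo <= phi:
            merged[-1] = (plo, max(phi, hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# CluPA-style hierarchical alignment
# ---------------------------------------------------------------------------

def _best_shift(ref: np.ndarray, seg: np.ndarray, max_shift: int) -> int:
    """Integer shift of ``seg`` (within +-max_shift) maximizing the
    Pearson correlation with ``ref``; zero shift wins ties."""
    r = ref - ref.mean()
    nr = float(np.linalg.norm(r))
    if nr == 0:
        return 0
    best, best_score = 0, -np.inf
    for s in sorted(range(-max_shift, max_shift + 1), key=abs):
        cand = _shift_edge_fill(seg, s)
        c = cand - cand.mean()
        nc = float(np.linalg.norm(c))
        if nc == 0:
            continue
        score = float(np.dot(r, c)) / (nr * nc)
        if score > best_score + 1e-12:
            best_score, best = score, s
    return best


def _has_interior_peak(seg: np.ndarray, margin: int, thr: float) -> bool:
    """True when the segment's maximum is a real apex away from the
    edges (tail-only segments must not be shifted)."""
    imax = int(np.argmax(seg))
    return margin < imax < seg.size - 1 - margin and seg[imax] > thr


def _align_segment(ref: np.ndarray, y: np.ndarray, lo: int, hi: int,
                   max_shift: int, min_width: int, noise: float) -> None:
    width = hi - lo
    if width < max(min_width, 3 * max_shift, 8):
        return
    rseg, yseg = ref[lo:hi], y[lo:hi]
    thr = 5.0 * noise
    if _has_interior_peak(rseg, max_shift, thr) and _has_interior_peak(
        yseg, max_shift, thr
    ):
        s = _best_shift(rseg, yseg, max_shift)
        if s != 0:
            y[lo:hi] = _shift_edge_fill(yseg, s)
            yseg = y[lo:hi]
    mid = (lo + hi) // 2
    _align_segment(ref, y, lo, mid, max_shift, min_width, noise)
    _align_segment(ref, y, mid, hi, max_shift, min_width, noise)


def _mean_pairwise_correlation(X: np.ndarray) -> float:
    c = np.corrcoef(X)
    n = c.shape[0]
    return float((c.sum() - n) / (n * (n - 1)))


def align_spectra(
    matrix: SpectraMatrix,
    segment_min_width: float = 0.1,
    max_shift: int = 25,
) -> SpectraMatrix:
    """CluPA-style hierarchical segment alignment.

    The reference is the sample with the highest correlation to the
    median spectrum.  Every other sample is aligned to it by integer
    grid shifts (|shift| <= ``max_shift`` points), recursing on segment
    halves down to ``segment_min_width`` ppm.  Guaranteed not to
    decrease the mean pairwise correlation: samples whose correlation to
    the reference drops are reverted, and if the overall mean pairwise
    correlation still drops the input is returned unchanged.
    """
    if max_shift <= 0:
        raise ValueError("max_shift must be > 0")
    if matrix.intensities.shape[0] < 2:
        raise ValueError("need at least 2 samples to align")
    out = matrix.copy()
    X = out.intensities
    median = np.median(X, axis=0)
    cors = [float(np.corrcoef(row, median)[0, 1]) for row in X]
    ref_idx = int(np.argmax(cors))
    ref = X[ref_idx]
    dx = abs(matrix.ppm[-1] - matrix.ppm[0]) / (matrix.ppm.size - 1)
    min_width = max(int(round(segment_min_width / dx)), 8)
    noise = float(np.median(np.abs(ref - np.median(ref)))) + 1e-12

    before = _mean_pairwise_correlation(matrix.intensities)
    for i in range(X.shape[0]):
        if i == ref_idx:
            continue
        y = X[i].copy()
        c0 = float(np.corrcoef(ref, y)[0, 1])
        _align_segment(ref, y, 0, y.size, max_shift, min_width, noise)
        if float(np.corrcoef(ref, y)[0, 1]) >= c0:
            X[i] = y
    after = _mean_pairwise_correlation(X)
    if after < before:
        log.warning("alignment did not improve mean correlation; reverted")
        return matrix.copy()
    log.info("alignment: mean pairwise correlation %.5f -> %.5f", before, after)
    return out


# ---------------------------------------------------------------------------
# Probabilistic quotient normalization
# ---------------------------------------------------------------------------

def pqn_normalize(
    matrix: SpectraMatrix,
    reference: str | np.ndarray = "median-spectrum",
    noise_floor: float | None = None,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Probabilistic quotient normalization.

    Each sample is first integral-normalized (to the cohort mean total
    integral), then divided by the median of its pointwise quotients
    against the reference spectrum, computed over unexcluded points
    where the reference exceeds ``noise_floor`` (default: the median of
    the reference over unexcluded points).  Returns the normalized
    matrix and the per-sample dilution factors (integral factor x
    median quotient), so a sample equal to c x reference gets factor c.
    """
    out = matrix.copy()
    X = out.intensities
    mask = out.unexcluded_mask()
    ppm = out.ppm

    totals = np.array([np.trapezoid(np.abs(row[mask]), ppm[mask]) for row in X])
    for i, t in enumerate(totals):
        if t == 0:
            raise ValueError(f"all-zero sample {out.sample_ids[i]!r}")
    mean_total = float(totals.mean())
    integral_factors = totals / mean_total
    Xn = X / integral_factors[:, None]

    if isinstance(reference, str):
        if reference != "median-spectrum":
            raise ValueError(f"unknown reference {reference!r}")
        ref = np.median(Xn, axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.size != ppm.size:
            raise ValueError("reference length must match the ppm axis")

    if np.mean(ref[mask] > 0) < 0.5:
        raise ValueError("reference spectrum not positive on >= 50% of points")
    if noise_floor is None:
        noise_floor = float(np.median(ref[mask]))
    valid = mask & (ref > noise_floor)
    if not valid.any():
        raise ValueError("no reference points above the noise floor")

    quotients = Xn[:, valid] / ref[valid]
    med_q = np.median(quotients, axis=1)
    out.intensities = Xn / med_q[:, None]
    factors = integral_factors * med_q
    return out, factors


# ---------------------------------------------------------------------------
# Intelligent (adaptive) bucketing
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    return np.convolve(np.pad(y, window // 2, mode="edge"), kernel, mode="valid")[: y.size]


def intelligent_bucket(
    matrix: SpectraMatrix,
    region: tuple[float, float] = (0.8, 8.5),
    min_width_ppm: float = 0.01,
    max_width_ppm: float = 0.5,
    snr_min: float = 3.0,
    noise_region: tuple[float, float] = (9.5, 10.0),
    smooth_points: int = 9,
) -> BucketTable:
    """Adaptive bucketing with edges at local minima of the mean spectrum.

    Edges are the local minima of the (lightly smoothed) mean spectrum
    inside ``region``; buckets narrower than ``min_width_ppm`` are merged
    into a neighbor, and buckets wider than ``max_width_ppm`` are split
    at their lowest interior point.  Bucket values are per-sample
    trapezoidal integrals.  Buckets are then filtered: the mean-spectrum
    maximum must reach ``snr_min`` times the noise (SD of the mean
    spectrum over ``noise_region``), and buckets intersecting an
    excluded region are dropped.  Dropped buckets stay available on the
    returned table for conservation checks.
    """
    ppm = matrix.ppm
    lo_ax, hi_ax = min(ppm[0], ppm[-1]), max(ppm[0], ppm[-1])
    rlo, rhi = region
    if rlo < lo_ax - 1e-9 or rhi > hi_ax + 1e-9 or rlo >= rhi:
        raise ValueError(f"bucketing region {region} outside the ppm axis")
    asc = ppm[0] < ppm[-1]
    X = matrix.intensities if asc else matrix.intensities[:, ::-1]
    ax = ppm if asc else ppm[::-1]

    mean = X.mean(axis=0)
    smooth = _moving_average(mean, smooth_points)

    i_lo = int(np.searchsorted(ax, rlo, side="left"))
    i_hi = int(np.searchsorted(ax, rhi, side="right")) - 1
    i_hi = min(i_hi, ax.size - 1)

    seg = smooth[i_lo : i_hi + 1]
    interior = np.flatnonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] < seg[2:])) + 1
    edges = [i_lo] + [i_lo + int(k) for k in interior] + [i_hi]
    edges = sorted(set(edges))

    dx = (ax[-1] - ax[0]) / (ax.size - 1)
    min_pts = max(int(round(min_width_ppm / dx)), 1)
    max_pts = max(int(round(max_width_ppm / dx)), 2 * min_pts)

    # merge too-narrow buckets: repeatedly drop the interior edge with the
    # highest smoothed intensity among edges bounding a narrow bucket
    edges = _enforce_min_width(edges, smooth, min_pts)
    edges = _enforce_max_width(edges, smooth, max_pts, min_pts)

    windows = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]

    noise = _noise_sd(mean, ax, noise_region, matrix)
    retained, dropped = [], []
    vals_r, vals_d = [], []
    excl = matrix.excluded_regions
    for a, b in windows:
        lo_p, hi_p = float(ax[a]), float(ax[b])
        integ = np.trapezoid(X[:, a : b + 1], ax[a : b + 1], axis=1)
        intersects = any(lo_p < ehi and hi_p > elo for elo, ehi in excl)
        ok_snr = mean[a : b + 1].max() >= snr_min * noise
        if ok_snr and not intersects:
            retained.append((lo_p, hi_p))
            vals_r.append(integ)
        else:
            dropped.append((lo_p, hi_p))
            vals_d.append(integ)

    order = np.argsort([-lo for lo, _ in retained]) if retained else []
    buckets = [retained[k] for k in order]
    values = (
        np.column_stack([vals_r[k] for k in order])
        if len(buckets)
        else np.zeros((matrix.intensities.shape[0], 0))
    )
    d_order = np.argsort([-lo for lo, _ in dropped]) if dropped else []
    log.info(
        "bucketing: %d buckets retained, %d dropped (S/N or exclusion)",
        len(buckets), len(dropped),
    )
    return BucketTable(
        buckets=buckets,
        values=values,
        sample_ids=list(matrix.sample_ids),
        groups=list(matrix.groups),
        dropped=[dropped[k] for k in d_order],
        dropped_values=(
            np.column_stack([vals_d[k] for k in d_order]) if dropped else None
        ),
    )


def _noise_sd(mean: np.ndarray, ax: np.ndarray,
              noise_region: tuple[float, float], matrix: SpectraMatrix) -> float:
    nlo, nhi = noise_region
    nmask = (ax >= nlo) & (ax <= nhi)
    if nmask.sum() >= 16:
        return float(np.std(mean[nmask])) + 1e-12
    # fall back to a robust global noise estimate when the stated region
    # is absent from the axis
    resid = mean - _moving_average(mean, 31)
    return float(1.4826 * np.median(np.abs(resid))) + 1e-12


def _enforce_min_width(edges: list[int], smooth: np.ndarray, min_pts: int) -> list[int]:
    edges = list(edges)
    while len(edges) > 2:
        widths = np.diff(edges)
        narrow = np.flatnonzero(widths < min_pts)
        if narrow.size == 0:
            break
        k = int(narrow[0])
        # remove whichever interior edge of this bucket sits higher
        cands = [e for e in (k, k + 1) if 0 < e < len(edges) - 1]
        if not cands:
            break
        drop = max(cands, key=lambda e: smooth[edges[e]])
        edges.pop(drop)
    return edges


def _enforce_max_width(edges: list[int], smooth: np.ndarray,
                       max_pts: int, min_pts: int) -> list[int]:
    out = [edges[0]]
    for a, b in zip(edges, edges[1:]):
        _split_wide(a, b, smooth, max_pts, min_pts, out)
        out.append(b)
    return sorted(set(out))


def _split_wide(a: int, b: int, smooth: np.ndarray,
                max_pts: int, min_pts: int, acc: list[int]) -> None:
    if b - a <= max_pts:
        return
    lo = a + min_pts
    hi = b - min_pts
    if hi <= lo:
        return
    cut = lo + int(np.argmin(smooth[lo : hi + 1]))
    _split_wide(a, cut, smooth, max_pts, min_pts, acc)
    acc.append(cut)
    _split_wide(cut, b, smooth, max_pts, min_pts, acc)
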