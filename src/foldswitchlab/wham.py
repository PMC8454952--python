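"""Weighted-histogram analysis of umbrella-sampling windows.

The solver is binless (MBAR-style self-consistent iteration over per-window
free-energy offsets), which handles windows run at different temperatures
and arbitrary harmonic biases in the same framework:

    exp(-f_k) = sum_x exp(-u_k(x)) / sum_l N_l exp(f_l - u_l(x)),

with reduced energies u_k(x) = beta_k [E0(x) + ½ k_k (q(x) - q0_k)²] over
all pooled frames x.  Unbiased frame weights at a target temperature then
give free-energy surfaces over any recorded coordinate(s), reweighted
averages, and heat-capacity curves C_v(T) = (<E²> - <E>²) / (k_B T²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax
from scipy.special import logsumexp

from ._kernels import KB


class WhamError(RuntimeError):
    pass


@dataclass
class UmbrellaWindowData:
    """Per-window time series feeding WHAM."""

    q0: float
    k: float
    temperature: float
    q_series: np.ndarray          # biased coordinate (Q_diff)
    e_series: np.ndarray          # unbiased potential energy, kcal/mol
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    equilibration_discard: int = 0
    seed: int | None = None
    failed: bool = False
    final_positions: np.ndarray | None = None  # bead coords at window end

    def __post_init__(self) -> None:
        self.q_series = np.asarray(self.q_series, float)
        self.e_series = np.asarray(self.e_series, float)
        if self.q_series.shape != self.e_series.shape:
            raise WhamError("q and E series lengths differ")
        if len(self.q_series) - self.equilibration_discard < 1:
            raise WhamError("no frames left after equilibration discard")

    @property
    def production_slice(self) -> slice:
        return slice(self.equilibration_discard, None)

    def bias(self, q: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (q - self.q0) ** 2


@dataclass
class WhamResult:
    offsets: np.ndarray            # f_k per window (dimensionless)
    q: np.ndarray                  # pooled production frames
    e: np.ndarray
    aux: dict[str, np.ndarray]
    log_denom: np.ndarray          # log sum_l N_l exp(f_l - u_l(x))
    n_iterations: int
    residual: float
    windows: list[UmbrellaWindowData]

    def weights(self, temperature: float) -> np.ndarray:
        """Normalized unbiased frame weights at the target temperature."""
        beta = 1.0 / (KB * temperature)
        logw = -beta * self.e - self.log_denom
        logw -= logsumexp(logw)
        return np.exp(logw)

    def expectation(self, values: np.ndarray, temperature: float) -> float:
        w = self.weights(temperature)
        return float(np.sum(w * np.asarray(values, float)))


def _check_overlap(windows: list[UmbrellaWindowData]) -> None:
    """Require the windows' sampled supports to form one connected graph.

    Two windows are connected when their sampled coordinate ranges overlap;
    WHAM can only stitch free energies across connected supports.
    """
    m = len(windows)
    spans = []
    for w in windows:
        q = w.q_series[w.production_slice]
        spans.append((q.min(), q.max()))
    # union-find over overlapping spans
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(m):
        for b in range(a + 1, m):
            if not (spans[a][0] > spans[b][1] or spans[b][0] > spans[a][1]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    roots = {find(i) for i in range(m)}
    if len(roots) > 1:
        groups = {}
        for i in range(m):
            groups.setdefault(find(i), []).append(windows[i].q0)
        lo_group = min(groups.values(), key=min)
        hi_group = max(groups.values(), key=min)
        raise WhamError(
            "umbrella histograms are not connected: gap between windows "
            f"around q0={max(lo_group):.3f} and q0={min(hi_group):.3f}")


def wham_solve(windows: list[UmbrellaWindowData], tol: float = 1e-7,
               max_iter: int = 100_000) -> WhamResult:
    """Self-consistent WHAM/MBAR offsets and pooled frame denominators.

    Failed windows must be excluded by the caller; a single unbiased window
    reduces to plain Boltzmann weighting (uniform at its own temperature).
    """
    windows = [w for w in windows if not w.failed]
    if not windows:
        raise WhamError("no usable windows")
    if len(windows) >= 2:
        _check_overlap(windows)

    q = np.concatenate([w.q_series[w.production_slice] for w in windows])
    e = np.concatenate([w.e_series[w.production_slice] for w in windows])
    aux = {}
    for key in windows[0].aux:
        aux[key] = np.concatenate([w.aux[key][w.production_slice]
                                   for w in windows])
    n_k = np.array([len(w.q_series[w.production_slice]) for w in windows],
                   float)
    # reduced energies u_k(x) for all frames x and windows k
    u = np.empty((len(windows), len(q)))
    for i, w in enumerate(windows):
        beta = 1.0 / (KB * w.temperature)
        u[i] = beta * (e + w.bias(q))

    f = np.zeros(len(windows))
    log_n = np.log(n_k)
    residual = np.inf
    for it in range(1, max_iter + 1):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise WhamError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.2e} > tol {tol:.0e})")
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    return WhamResult(offsets=f, q=q, e=e, aux=aux, log_denom=log_denom,
                      n_iterations=it, residual=residual, windows=windows)


@dataclass
class FreeEnergySurface:
    """Binned free energies (kcal/mol) over 1-2 reaction coordinates.

    Unsampled bins are NaN with ``mask`` False; the sampled minimum is 0.
    """

    axes: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    f: np.ndarray
    mask: np.ndarray
    temperature: float

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def to_tsv(self, path) -> None:
        import pandas as pd
        cols = {}
        grids = np.meshgrid(*self.centers, indexing="ij")
        for name, g in zip(self.axes, grids):
            cols[name] = g.ravel()
        cols["free_energy"] = self.f.ravel()
        cols["sampled"] = self.mask.ravel().astype(int)
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def project_fes(result: WhamResult, axes: tuple[str, ...],
                temperature: float,
                bins: int | tuple = 50,
                ranges: tuple | None = None) -> FreeEnergySurface:
    """F(bin) = -k_B T ln sum of unbiased weights, minimum shifted to 0.

    Axis names: ``"qdiff"``, ``"energy"`` or any recorded aux key.
    """
    if not 1 <= len(axes) <= 2:
        raise WhamError("1 or 2 axes required")

    def values(name: str) -> np.ndarray:
        if name == "qdiff":
            return result.q
        if name == "energy":
            return result.e
        if name in result.aux:
            return result.aux[name]
        raise WhamError(f"axis {name!r} not present in frames "
                        f"(have: qdiff, energy, {sorted(result.aux)})")

    sample = np.stack([values(a) for a in axes], axis=1)
    w = result.weights(temperature)
    hist, edges = np.histogramdd(sample, bins=bins, range=ranges, weights=w)
    mask = hist > 0
    f = np.full(hist.shape, np.nan)
    f[mask] = -KB * temperature * np.log(hist[mask])
    f[mask] -= np.nanmin(f[mask])
    return FreeEnergySurface(axes=tuple(axes), edges=tuple(edges), f=f,
                             mask=mask, temperature=temperature)


def heat_capacity(result: WhamResult, temperatures: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C_v(T) from reweighted energy fluctuations; returns (T, C_v, peaks).

    Peaks are the temperatures of local maxima in scan order; the first
    peak of the designated folded system defines T_f.  Temperatures far
    outside the sampled range are an extrapolation and should be read with
    care.
    """
    temperatures = np.asarray(temperatures, float)
    cv = np.empty_like(temperatures)
    for i, t in enumerate(temperatures):
        e1 = result.expectation(result.e, t)
        e2 = result.expectation(result.e ** 2, t)
        cv[i] = max(e2 - e1 * e1, 0.0) / (KB * t * t)
    peak_idx = argrelmax(cv)[0]
    return temperatures, cv, temperatures[peak_idx]


def histogram_overlap_report(windows: list[UmbrellaWindowData],
                             bins: int = 50,
                             min_overlap: float = 0.05,
                             off_center_tol: float = 0.15) -> list[dict]:
    """Shared-support fraction for each adjacent window pair.

    Overlap is the integral of the minimum of the two normalized
    histograms (1 for identical distributions, 0 for disjoint).  Windows
    whose mean coordinate sits far off their bias center are annotated as
    trapped candidates for exclusion.
    """
    windows = sorted(windows, key=lambda w: w.q0)
    report = []
    for a, b in zip(windows[:-1], windows[1:]):
        qa = a.q_series[a.production_slice]
        qb = b.q_series[b.production_slice]
        lo = min(qa.min(), qb.min())
        hi = max(qa.max(), qb.max())
        if hi == lo:
            overlap = 1.0 if qa.min() == qb.min() else 0.0
        else:
            edges = np.linspace(lo, hi, bins + 1)
            pa, _ = np.histogram(qa, bins=edges, density=True)
            pb, _ = np.histogram(qb, bins=edges, density=True)
            overlap = float(np.minimum(pa, pb).sum() * (edges[1] - edges[0]))
        report.append({
            "q0_left": a.q0, "q0_right": b.q0, "overlap": overlap,
            "ok": overlap >= min_overlap,
            "left_trapped": bool(abs(qa.mean() - a.q0) > off_center_tol
                                 or a.failed),
            "right_trapped": bool(abs(qb.mean() - b.q0) > off_center_tol
                                  or b.failed),
        })
    return report
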