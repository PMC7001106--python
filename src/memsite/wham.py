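"""Weighted histogram analysis method (WHAM) and PMF post-processing.

:class:`WHAM` follows the statsmodels convention: construct the model
from data (an :class:`~memsite.umbrella.UmbrellaSet`), call
:meth:`WHAM.fit`, and work with the returned :class:`PMFResult`, which
carries the profile, window free energies, convergence diagnostics,
bulk-zeroing, well-depth extraction, bootstrap errors and plotting.

The estimator solves the standard self-consistent equations for
binned umbrella data,

    p_j = M_j / sum_i N_i exp(beta f_i) c_ij,
    exp(-beta f_i) = sum_j c_ij p_j,      c_ij = exp(-beta b_i(x_j)),

iterated until the largest window free-energy shift drops below a
tolerance; G(s) = -k_B T ln p(s), referenced so the mean over a bulk
interval is exactly zero.

Because the planted site wells are radial in the membrane plane while
the PMF is one-dimensional, the raw profile contains the free energy
of the lateral (off-axis) coordinate.  :meth:`PMFResult.lateral_corrected`
removes it using the per-window lateral spread actually sampled:
G(s) <- G(s) + k_B T ln(w(s)/w_bulk).  After this correction the PMF
minimum equals the planted well amplitude in the dilute limit, which
is what makes planted-depth recovery a meaningful test.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import kBT
from .umbrella import UmbrellaSet

__all__ = [
    "WHAM",
    "PMFResult",
    "ConvergenceError",
    "well_depth",
    "ddg_from_pmfs",
    "convergence_by_duration",
    "bootstrap_well_depth_error",
    "DEFAULT_BULK_INTERVAL",
]

#: Default bulk reference interval (nm): the outermost 0.5 nm of the
#: canonical window range.
DEFAULT_BULK_INTERVAL = (2.5, 3.0)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PMFResult:
    """A reconstructed free-energy profile.

    ``pmf`` is G(s) in kJ/mol on uniform ``bins``; ``window_f`` the
    per-window free energies (kJ/mol); ``errors`` optional per-bin
    bootstrap SDs filled in by :meth:`bootstrap_errors`.
    """

    bins: np.ndarray  # (B,) bin centers, nm
    pmf: np.ndarray  # (B,) kJ/mol
    window_f: np.ndarray
    temperature: float
    n_iter: int
    converged: bool
    counts: np.ndarray | None = None  # (B,) pooled histogram
    errors: np.ndarray | None = None
    bulk_interval: tuple | None = None
    lateral_correction_applied: bool = False

    def _bulk_mask(self, bulk_interval) -> np.ndarray:
        lo, hi = bulk_interval
        mask = (self.bins >= lo) & (self.bins <= hi) & np.isfinite(self.pmf)
        if not mask.any():
            raise ValueError(
                f"bulk interval {bulk_interval} lies outside the profile "
                f"range [{self.bins[0]:.3g}, {self.bins[-1]:.3g}]"
            )
        return mask

    def zeroed(self, bulk_interval=DEFAULT_BULK_INTERVAL) -> "PMFResult":
        """Reference the profile so mean G over the bulk interval is 0."""
        mask = self._bulk_mask(bulk_interval)
        shift = self.pmf[mask].mean()
        return replace(self, pmf=self.pmf - shift, bulk_interval=tuple(bulk_interval))

    def lateral_corrected(self, uset: UmbrellaSet,
                          bulk_interval=DEFAULT_BULK_INTERVAL) -> "PMFResult":
        """Remove the lateral (off-axis) free energy from the profile.

        The per-window lateral spread w_i = std(y_i) is interpolated
        along the mean sampled coordinate and G(s) is corrected by
        +k_B T ln(w(s)/w_bulk), with w_bulk averaged over windows whose
        centers lie in the bulk interval.  Where the lateral spread is
        constant the correction vanishes identically.
        """
        kT = kBT(self.temperature)
        w = uset.y.std(axis=1)
        if np.any(w <= 0):
            raise ValueError("cannot apply lateral correction: zero lateral spread")
        pos = uset.s.mean(axis=1)
        order = np.argsort(pos)
        lnw = np.interp(self.bins, pos[order], np.log(w[order]))
        bulk = (uset.centers >= bulk_interval[0]) & (uset.centers <= bulk_interval[1])
        if not bulk.any():
            bulk = uset.centers >= np.quantile(uset.centers, 0.8)
        lnw_bulk = np.log(w[bulk]).mean()
        corrected = self.pmf + kT * (lnw - lnw_bulk)
        return replace(self, pmf=corrected, lateral_correction_applied=True)

    def well_depth(self, bulk_interval=DEFAULT_BULK_INTERVAL) -> float:
        return well_depth(self, bulk_interval)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"s": self.bins, "G": self.pmf})
        if self.errors is not None:
            df["err"] = self.errors
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "PMF reconstruction (WHAM)",
            "=" * 41,
            f"bins:                 {len(self.bins)} "
            f"[{self.bins[0]:.3f}, {self.bins[-1]:.3f}] nm",
            f"temperature:          {self.temperature:.1f} K",
            f"iterations:           {self.n_iter} "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"lateral correction:   {'applied' if self.lateral_correction_applied else 'no'}",
            f"bulk interval:        {self.bulk_interval}",
        ]
        finite = np.isfinite(self.pmf)
        if finite.any():
            imin = int(np.nanargmin(np.where(finite, self.pmf, np.nan)))
            depth = self.pmf[imin]
            err = f" +/- {self.errors[imin]:.2f}" if self.errors is not None else ""
            lines.append(f"minimum:              G({self.bins[imin]:.3f} nm) = "
                         f"{depth:.2f}{err} kJ/mol")
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.errors is not None:
            ax.fill_between(self.bins, self.pmf - self.errors,
                            self.pmf + self.errors, alpha=0.3)
        ax.plot(self.bins, self.pmf, **kwargs)
        ax.set_xlabel("reaction coordinate s (nm)")
        ax.set_ylabel("G(s) (kJ/mol)")
        return ax


class WHAM:
    """WHAM model over a set of umbrella windows.

    Parameters
    ----------
    uset
        Window samples (centers, force constant, reaction-coordinate
        series).
    bin_width
        Histogram bin width (nm); 0.05 by default, half the canonical
        window spacing.
    bin_range
        Optional (lo, hi); defaults to the sampled range.
    """

    def __init__(self, uset: UmbrellaSet, bin_width: float = 0.05,
                 bin_range: tuple | None = None,
                 temperature: float | None = None):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.uset = uset
        self.bin_width = bin_width
        self.temperature = temperature if temperature is not None else uset.temperature
        lo, hi = bin_range if bin_range is not None else (uset.s.min(), uset.s.max())
        n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
        self.edges = lo + np.arange(n_bins + 1) * bin_width
        self.bins = 0.5 * (self.edges[:-1] + self.edges[1:])

    def _check_overlap(self) -> None:
        s = self.uset.s
        order = np.argsort(self.uset.centers)
        lo, hi = s.min(axis=1), s.max(axis=1)
        for a, b in zip(order[:-1], order[1:]):
            if min(hi[a], hi[b]) < max(lo[a], lo[b]):
                raise ConvergenceError(
                    "non-overlapping window histograms between centers "
                    f"{self.uset.centers[a]:.3f} and {self.uset.centers[b]:.3f} nm; "
                    "WHAM cannot bridge the gap"
                )

    def fit(self, tol: float = 1e-8, max_iter: int = 100_000) -> PMFResult:
        """Iterate the self-consistent equations to convergence.

        ``tol`` is the largest window free-energy change per iteration,
        in kJ/mol.  Deterministic given the samples.
        """
        self._check_overlap()
        uset = self.uset
        kT = kBT(self.temperature)
        beta = 1.0 / kT
        W = uset.n_windows
        N = np.full(W, uset.n_samples, dtype=float)
        M = np.zeros(len(self.bins))
        for i in range(W):
            hist, _ = np.histogram(uset.s[i], bins=self.edges)
            M += hist
        # bias factors c_ij = exp(-beta * k/2 (x_j - c_i)^2); underflow
        # to 0 is exact for unreachable bins
        with np.errstate(under="ignore"):
            c = np.exp(-beta * 0.5 * uset.k
                       * (self.bins[None, :] - uset.centers[:, None]) ** 2)
        g = np.ones(W)  # exp(beta f_i)
        n_iter = 0
        converged = False
        with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
            for n_iter in range(1, max_iter + 1):
                denom = (N * g) @ c  # (B,)
                p = np.where(denom > 0, M / denom, 0.0)
                z = c @ p  # exp(-beta f_i)
                g_new = 1.0 / z
                shift = kT * np.max(np.abs(np.log(g_new) - np.log(g)))
                g = g_new
                if shift < tol:
                    converged = True
                    break
            p_sum = p.sum()
            p = p / p_sum if p_sum > 0 else p
            pmf = np.where(p > 0, -kT * np.log(p), np.inf)
        if not converged:
            raise ConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {shift:.2e} kJ/mol)"
            )
        pmf = pmf - pmf[np.isfinite(pmf)].min()
        window_f = -kT * np.log(np.maximum(1.0 / g, 1e-300))
        return PMFResult(bins=self.bins.copy(), pmf=pmf, window_f=window_f,
                         temperature=self.temperature, n_iter=n_iter,
                         converged=converged, counts=M)


def well_depth(pmf: PMFResult, bulk_interval=DEFAULT_BULK_INTERVAL) -> float:
    """min G minus the mean G over the bulk interval (kJ/mol).

    Equals min(G) for an already bulk-zeroed profile; more negative
    means stronger binding.
    """
    mask = pmf._bulk_mask(bulk_interval)
    finite = np.isfinite(pmf.pmf)
    return float(pmf.pmf[finite].min() - pmf.pmf[mask].mean())


def ddg_from_pmfs(pmf_a: PMFResult, pmf_b: PMFResult,
                  bulk_interval=DEFAULT_BULK_INTERVAL) -> float:
    """Relative binding free energy for converting species A -> B.

    well_depth(B) - well_depth(A); positive means B binds more weakly.
    """
    return well_depth(pmf_b, bulk_interval) - well_depth(pmf_a, bulk_interval)


def _fit_protocol(uset: UmbrellaSet, bin_width: float,
                  bulk_interval, lateral_correction: bool) -> PMFResult:
    res = WHAM(uset, bin_width=bin_width).fit()
    if lateral_correction:
        res = res.lateral_corrected(uset, bulk_interval)
    return res.zeroed(bulk_interval)


def convergence_by_duration(
    uset: UmbrellaSet,
    checkpoints,
    bin_width: float = 0.05,
    bulk_interval=DEFAULT_BULK_INTERVAL,
    lateral_correction: bool = True,
):
    """PMFs on truncated sample prefixes, plus successive deviations.

    ``checkpoints`` (sample counts) are sorted internally.  Returns
    (checkpoints, profiles, deviations) where deviations[i] is the
    largest |Delta G| between checkpoint i and i+1 over bins finite in
    both -- the standard "has the PMF stopped drifting with more
    sampling" diagnostic.
    """
    cps = sorted(int(c) for c in checkpoints)
    if cps[-1] > uset.n_samples:
        raise ValueError(f"checkpoint {cps[-1]} exceeds available samples "
                         f"{uset.n_samples}")
    profiles = [_fit_protocol(uset.truncated(c), bin_width, bulk_interval,
                              lateral_correction) for c in cps]
    deviations = []
    for a, b in zip(profiles[:-1], profiles[1:]):
        # compare on the better-sampled profile's grid, restricted to
        # bins both checkpoints populated adequately
        ok_a = np.isfinite(a.pmf) & (a.counts >= 10)
        ok_b = np.isfinite(b.pmf) & (b.counts >= 10)
        if not (ok_a.any() and ok_b.any()):
            deviations.append(np.inf)
            continue
        lo = max(a.bins[ok_a].min(), b.bins[ok_b].min())
        hi = min(a.bins[ok_a].max(), b.bins[ok_b].max())
        grid = b.bins[ok_b & (b.bins >= lo) & (b.bins <= hi)]
        if grid.size == 0:
            deviations.append(np.inf)
            continue
        ga = np.interp(grid, a.bins[ok_a], a.pmf[ok_a])
        gb = np.interp(grid, b.bins[ok_b], b.pmf[ok_b])
        deviations.append(float(np.max(np.abs(ga - gb))))
    return cps, profiles, np.array(deviations)


def _integrated_autocorr(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time (in samples) by the initial
    positive sequence, capped self-consistently (Sokal window)."""
    x = x - x.mean()
    n = len(x)
    if n < 4 or np.allclose(x, 0):
        return 1.0
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    if acf[0] <= 0:
        return 1.0
    acf /= acf[0]
    tau = 1.0
    for m in range(1, n):
        tau += 2.0 * acf[m]
        if m >= c * tau:
            break
    return max(tau, 1.0)


def bootstrap_well_depth_error(
    uset: UmbrellaSet,
    n_boot: int = 32,
    seed: int = 0,
    block_length: int | None = None,
    bin_width: float = 0.05,
    bulk_interval=DEFAULT_BULK_INTERVAL,
    lateral_correction: bool = True,
) -> float:
    """Block-bootstrap SD of the well depth (kJ/mol).

    Each window's sample series is resampled in contiguous blocks whose
    length defaults to twice the largest integrated autocorrelation
    time across windows, so resampled draws are effectively
    independent; the full analysis (WHAM, lateral correction, bulk
    zeroing, well depth) is repeated per resample.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    n = uset.n_samples
    if block_length is None:
        taus = [_integrated_autocorr(uset.s[i]) for i in range(uset.n_windows)]
        block_length = int(min(max(2 * max(taus), 10), n))
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_length))
    depths = []
    for _ in range(n_boot):
        s_b = np.empty_like(uset.s)
        y_b = np.empty_like(uset.y)
        for i in range(uset.n_windows):
            starts = rng.integers(0, max(n - block_length, 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()[:n]
            s_b[i] = uset.s[i, idx]
            y_b[i] = uset.y[i, idx]
        boot = replace(uset, s=s_b, y=y_b)
        depths.append(_fit_protocol(boot, bin_width, bulk_interval,
                                    lateral_correction).well_depth(bulk_interval))
    return float(np.std(depths, ddof=1))
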