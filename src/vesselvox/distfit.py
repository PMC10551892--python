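"""Frequency distributions of segment-level descriptors and law fitting.

A single network yields thousands of segments, so segment-level descriptors
(length, diameter, tortuosity) are best characterized by their frequency
distribution rather than a single summary value. Capillary segment length
and tortuosity distributions are typically well described by a first-order
exponential decay, and diameter distributions by a Gaussian; a power law is
offered as an optional candidate but self-similar structures do not imply
power-law descriptor distributions.

Counts (not densities) are fitted, so the amplitude parameter absorbs the
sample size and bin width; shape parameters (tau, mu, sigma) are invariant
under count rescaling. Candidate laws are ranked by AIC with r² as the
tiebreak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyDistribution",
    "LawFit",
    "DistFitError",
    "frequency_distribution",
    "fit_law",
    "select_best_law",
    "LAWS",
]


class DistFitError(Exception):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FrequencyDistribution:
    """Uniform-bin histogram of a segment-level descriptor."""

    variable: str  # "length" | "diameter" | "tortuosity" | free-form
    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float


@dataclass
class LawFit:
    law: str
    params: dict[str, float]
    r_squared: float
    aic: float


def _freedman_diaconis_width(values: np.ndarray) -> float:
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    if iqr <= 0:
        return max(float(values.std()) / 2, np.finfo(float).eps)
    return float(2 * iqr / len(values) ** (1 / 3))


def frequency_distribution(
    values,
    variable: str = "value",
    bin_width: float | None = None,
    bin_count: int | None = None,
) -> FrequencyDistribution:
    """Exact-count histogram with uniform, left-closed bins.

    Bin edges start at the minimum value; each bin is ``[lo, lo + w)``
    except the last, which is closed. Default bin width is the
    Freedman–Diaconis rule. Warns below 50 values; fails on empty input.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DistFitError("cannot build a frequency distribution of zero values")
    if values.size < 50:
        logger.warning("only %d values; frequency distribution will be noisy", values.size)
    lo, hi = float(values.min()), float(values.max())
    if bin_width is None and bin_count is None:
        bin_width = _freedman_diaconis_width(values)
    if bin_width is not None:
        if bin_width <= 0:
            raise DistFitError(f"bin width must be positive, got {bin_width}")
        n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    else:
        if bin_count < 1:
            raise DistFitError(f"bin count must be >= 1, got {bin_count}")
        n_bins = int(bin_count)
        bin_width = (hi - lo) / n_bins if hi > lo else 1.0
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return FrequencyDistribution(
        variable=variable,
        bin_centers=centers,
        counts=counts.astype(np.int64),
        bin_width=float(bin_width),
    )


def _exp_decay(x, a, tau, y0, x0=0.0):
    # anchored at x0 (the first bin) so amplitude and tau stay decorrelated
    return a * np.exp(-(x - x0) / tau) + y0


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def _power_law(x, a, k):
    return a * np.power(x, -k)


#: Candidate laws in tie-break order (exponential before gaussian).
LAWS = ("exponential_decay", "gaussian", "power_law")


def fit_law(fd: FrequencyDistribution, law: str, offset: bool = True) -> LawFit:
    """Non-linear least-squares fit of a candidate law to the bin counts.

    Initialization is moments-based and the fit is deterministic. For
    ``exponential_decay`` the model is ``A*exp(-x/tau) + y0`` with
    ``A, tau > 0`` and ``y0 >= 0``; pass ``offset=False`` to pin y0 at 0.
    The Gaussian model is ``A*exp(-(x-mu)^2/(2 sigma^2))`` with sigma > 0.
    """
    x = fd.bin_centers.astype(float)
    y = fd.counts.astype(float)
    if int((y > 0).sum()) < 5:
        raise DistFitError(f"need >= 5 non-empty bins, got {(y > 0).sum()}")

    w = y / y.sum()
    m = float((w * x).sum())
    s = float(np.sqrt((w * (x - m) ** 2).sum())) or fd.bin_width

    if law == "exponential_decay":
        x0 = float(x.min())
        tau0 = max(m - x0, fd.bin_width)
        if offset:
            p0 = (float(y.max()), tau0, 0.0)
            bounds = ((1e-12, 1e-12, 0.0), (np.inf, np.inf, np.inf))
            model = lambda xx, a, tau, y0: _exp_decay(xx, a, tau, y0, x0)
            names = ("amplitude", "tau", "y0")
        else:
            p0 = (float(y.max()), tau0)
            bounds = ((1e-12, 1e-12), (np.inf, np.inf))
            model = lambda xx, a, tau: _exp_decay(xx, a, tau, 0.0, x0)
            names = ("amplitude", "tau")
    elif law == "gaussian":
        # a Gaussian law describes a peaked distribution: the mode must lie
        # within the observed support, otherwise the fit degenerates into a
        # monotone tail indistinguishable from an exponential decay
        p0 = (float(y.max()), min(max(m, x.min()), x.max()), s)
        bounds = ((1e-12, x.min(), 1e-12), (np.inf, x.max(), np.inf))
        model, names = _gaussian, ("amplitude", "mu", "sigma")
    elif law == "power_law":
        if (x <= 0).any():
            raise DistFitError("power law requires strictly positive bin centers")
        p0 = (float(y.max()) * x.min(), 1.0)
        bounds = ((1e-12, 1e-12), (np.inf, np.inf))
        model, names = _power_law, ("amplitude", "exponent")
    else:
        raise DistFitError(f"unknown law {law!r}; choose from {LAWS}")

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise DistFitError(
            f"{law} fit did not converge", diagnostics={"error": str(exc), "p0": p0}
        ) from exc

    pred = model(x, *popt)
    resid = y - pred
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n, k = len(x), len(popt)
    aic = n * np.log(max(ss_res, 1e-300) / n) + 2 * k
    return LawFit(
        law=law,
        params={name: float(v) for name, v in zip(names, popt)},
        r_squared=r2,
        aic=float(aic),
    )


def select_best_law(
    fd: FrequencyDistribution,
    candidates=("exponential_decay", "gaussian"),
    offset: bool = True,
) -> list[LawFit]:
    """Fit all candidate laws and rank them, best first.

    Ranking is by AIC (lower better) with r² (higher better) as tiebreak;
    on an exact tie the documented candidate order (exponential before
    gaussian) is preserved. All successful fits are returned.
    """
    if len(candidates) < 2:
        raise DistFitError("need at least 2 candidate laws")
    fits: list[tuple[int, LawFit]] = []
    errors: dict[str, str] = {}
    rank_order = {law: i for i, law in enumerate(LAWS)}
    for law in candidates:
        try:
            fits.append((rank_order.get(law, len(LAWS)), fit_law(fd, law, offset=offset)))
        except DistFitError as exc:
            errors[law] = str(exc)
    if not fits:
        raise DistFitError(f"all candidate fits failed: {errors}")
    fits.sort(key=lambda t: (t[1].aic, -t[1].r_squared, t[0]))
    return [f for _, f in fits]
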