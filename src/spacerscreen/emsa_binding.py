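"""Hill-model analysis of EMSA titrations.

An electrophoretic mobility shift assay titrates RNA polymerase holoenzyme
against a labelled promoter fragment.  Band densitometry gives, per lane,
the intensity of the shifted (bound) and unshifted (free) bands; the
fraction bound follows the Hill equation

    theta(P) = P^n / (Kd^n + P^n)

where P is the total polymerase concentration (nM), Kd the dissociation
constant (nM) and n the Hill coefficient.  Fits are per replicate; the
reported Kd is the mean of the per-replicate fits and its uncertainty the
standard error over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BindingSeries", "HillFit", "fraction_bound", "hill", "fit_hill"]

log = logging.getLogger(__name__)


def hill(p, kd, n):
    """Hill equation: fraction bound at total polymerase concentration p (nM)."""
    p = np.asarray(p, dtype=float)
    return p**n / (kd**n + p**n)


@dataclass(frozen=True)
class BindingSeries:
    """One EMSA titration: concentrations (nM) x replicate fraction-bound matrix.

    ``theta`` has shape (n_replicates, n_concentrations), all values in [0, 1].
    """

    concentrations: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if conc.ndim != 1 or np.any(conc <= 0):
            raise ValueError("concentrations must be a 1-D strictly positive vector (nM)")
        if theta.shape[1] != conc.size:
            raise ValueError("theta must have one column per concentration")
        if np.any(theta < 0) or np.any(theta > 1):
            raise ValueError("fraction bound must lie in [0, 1]")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "theta", theta)

    @property
    def n_replicates(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class HillFit:
    """Result of per-replicate Hill fits.

    ``kd`` is the mean of the per-replicate dissociation constants (nM) and
    ``kd_se`` their standard error; ``n_hill`` is the mean fitted Hill
    coefficient.  Replicates that fail to converge are recorded in
    ``flagged_replicates`` and excluded from the summaries.
    """

    kd: float
    n_hill: float
    per_replicate_kd: np.ndarray
    per_replicate_n: np.ndarray
    kd_se: float
    rss: float
    flagged_replicates: tuple[int, ...] = field(default=())


def fraction_bound(bound_intensity, free_intensity, background) -> float:
    """Fraction bound from band intensities after background subtraction.

    theta = (bound - bg) / ((bound - bg) + (free - bg)), clipped to [0, 1];
    clipping events are logged.  Both corrected intensities zero is
    undefined and raises.
    """
    b = float(bound_intensity) - float(background)
    f = float(free_intensity) - float(background)
    if b == 0.0 and f == 0.0:
        raise ValueError("both corrected band intensities are zero; fraction bound undefined")
    theta = b / (b + f)
    if theta < 0.0 or theta > 1.0:
        log.warning("fraction bound %.3f outside [0,1]; clipped", theta)
        theta = min(max(theta, 0.0), 1.0)
    return theta


def _fit_one(conc: np.ndarray, theta: np.ndarray) -> tuple[float, float, float]:
    """Least-squares Hill fit of a single replicate; returns (kd, n, rss)."""
    kd0 = float(conc[np.argmin(np.abs(theta - 0.5))])
    kd_hi = 100.0 * float(conc.max())
    kd0 = min(max(kd0, 1e-9), kd_hi)
    popt, _ = curve_fit(
        hill,
        conc,
        theta,
        p0=[kd0, 1.0],
        bounds=([1e-9, 1e-9], [kd_hi, 10.0]),
        maxfev=10000,
    )
    resid = theta - hill(conc, *popt)
    return float(popt[0]), float(popt[1]), float(resid @ resid)


def fit_hill(series: BindingSeries) -> HillFit:
    """Fit the Hill equation to each replicate of a titration.

    Initialization: Kd at the concentration nearest half-saturation, n = 1;
    bounds Kd in (0, 100 x max concentration], n in (0, 10].  Replicates
    whose fit does not converge (or is degenerate, e.g. flat theta) are
    flagged and excluded; if every replicate fails, an error is raised.
    """
    if np.unique(series.concentrations).size < 4:
        raise ValueError("Hill fitting needs at least 4 distinct concentrations")
    kds, ns, rss, flagged = [], [], 0.0, []
    for i in range(series.n_replicates):
        if np.ptp(series.theta[i]) < 0.05:
            # no titration signal: the Hill model is unidentifiable
            log.warning("replicate %d: flat fraction-bound profile; excluded", i)
            flagged.append(i)
            continue
        try:
            kd_i, n_i, rss_i = _fit_one(series.concentrations, series.theta[i])
        except RuntimeError:
            log.warning("replicate %d: Hill fit did not converge; excluded", i)
            flagged.append(i)
            continue
        # a fit pinned to the Kd upper bound means the data carry no
        # saturation information (e.g. constant theta) -> degenerate
        if kd_i >= 0.999 * 100.0 * float(series.concentrations.max()):
            log.warning("replicate %d: degenerate fit (Kd at bound); excluded", i)
            flagged.append(i)
            continue
        kds.append(kd_i)
        ns.append(n_i)
        rss += rss_i
    if not kds:
        raise ValueError("Hill fit failed for every replicate")
    kds_arr = np.array(kds)
    ns_arr = np.array(ns)
    se = float(kds_arr.std(ddof=1) / np.sqrt(kds_arr.size)) if kds_arr.size > 1 else 0.0
    return HillFit(
        kd=float(kds_arr.mean()),
        n_hill=float(ns_arr.mean()),
        per_replicate_kd=kds_arr,
        per_replicate_n=ns_arr,
        kd_se=se,
        rss=rss,
        flagged_replicates=tuple(flagged),
    )
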