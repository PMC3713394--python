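"""From magnitude series to Gamma-plane points.

The estimation unit is the "data entry": a block of (by default) 100
consecutive max-deviation magnitudes.  Each entry's empirical distribution
is screened for unimodality with Hartigan's dip test (multimodal entries,
p < 0.01, are discarded as contaminated), then fit by maximum likelihood
with the two-parameter Gamma family

    f(x | a, b) = x**(a-1) * exp(-x/b) / (b**a * Gamma(a)),   x > 0,

where ``a`` is the shape and ``b`` the scale.  Each surviving entry thus
becomes one (a, b) point with 95% confidence intervals — one step of the
person's stochastic trajectory on the Gamma plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .accel_io import MagnitudeSeries
from .dip import dip_test

__all__ = [
    "DataEntry",
    "GammaEstimate",
    "chunk_entries",
    "optimal_bin_width",
    "gamma_pdf",
    "fit_gamma_mle",
    "entry_signatures",
    "DEFAULT_WINDOW",
    "DEFAULT_DIP_ALPHA",
    "MIN_ENTRIES_PER_PARTICIPANT",
]

DEFAULT_WINDOW = 100
DEFAULT_DIP_ALPHA = 0.01
#: Participants with fewer surviving entries than this are flagged for
#: exclusion from the cohort stage: too few trajectory points for a
#: meaningful per-person peak distribution.
MIN_ENTRIES_PER_PARTICIPANT = 20

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DataEntry:
    """One estimation block of consecutive magnitudes."""

    entry_index: int  # 1-based, acquisition order
    samples: np.ndarray
    provenance: tuple[str, int, int]  # (participant, day, session of first value)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.entry_index < 1:
            raise ValueError("entry_index is 1-based")
        if not np.all(np.isfinite(self.samples)) or np.any(self.samples < 0):
            raise ValueError("entry samples must be finite and >= 0")


@dataclass(frozen=True)
class GammaEstimate:
    """Fitted Gamma (shape, scale) with 95% CIs for one sample.

    ``mean`` and ``variance`` are the model moments a*b and a*b**2, so the
    variance-to-mean ratio (Fano factor) equals the scale b identically.
    """

    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n: int
    dip_p: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("shape and scale must be positive")
        if not (self.ci_a[0] <= self.a <= self.ci_a[1]):
            raise ValueError("shape outside its own CI")
        if not (self.ci_b[0] <= self.b <= self.ci_b[1]):
            raise ValueError("scale outside its own CI")

    @property
    def mean(self) -> float:
        return self.a * self.b

    @property
    def variance(self) -> float:
        return self.a * self.b**2


class EstimationError(RuntimeError):
    """MLE failed to converge or produced a degenerate estimate."""


def chunk_entries(
    series: MagnitudeSeries, window: int = DEFAULT_WINDOW
) -> list[DataEntry]:
    """Split a magnitude series into disjoint consecutive entries.

    A trailing remainder shorter than ``window`` is discarded.  Entries
    never span participants (a series belongs to one participant by
    construction); they may span sessions and days, which the trajectory
    stage tags via the entry's provenance.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n_full = len(series) // window
    if n_full == 0:
        warnings.warn(
            f"series of {series.participant_id} shorter than window "
            f"({len(series)} < {window}); no entries",
            stacklevel=2,
        )
        return []
    entries = []
    for i in range(n_full):
        lo = i * window
        day, ses = series.provenance[lo]
        entries.append(
            DataEntry(
                entry_index=i + 1,
                samples=series.values[lo : lo + window],
                provenance=(series.participant_id, day, ses),
            )
        )
    return entries


def optimal_bin_width(samples) -> float:
    """Scott-style histogram bin width W = 3.49 * sigma_hat * N**(-1/3)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples for a bin width")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate input: sample standard deviation is zero")
    return 3.49 * sd * x.size ** (-1.0 / 3.0)


def gamma_pdf(x, a: float, b: float):
    """Gamma density x**(a-1) exp(-x/b) / (b**a Gamma(a)) for x > 0."""
    if not (a > 0 and b > 0):
        raise ValueError("shape and scale must be positive")
    x = np.asarray(x, dtype=float)
    out = stats.gamma.pdf(x, a, loc=0.0, scale=b)
    return float(out) if out.ndim == 0 else out


def fit_gamma_mle(samples, dip_p: float = float("nan")) -> GammaEstimate:
    """Gamma MLE with location fixed at 0 and Wald-on-log 95% CIs.

    The CIs come from the observed Fisher information of the Gamma
    log-likelihood at the MLE,

        I(a, b) = n * [[psi'(a), 1/b], [1/b, a/b**2]],

    delta-transformed to (log a, log b) so the exponentiated intervals
    stay positive and respect the scale's skew.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 samples to fit, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("samples must be strictly positive and finite")
    a, loc, b = stats.gamma.fit(x, floc=0.0)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise EstimationError(f"gamma MLE did not converge: a={a}, b={b}")

    n = x.size
    info = n * np.array([[special.polygamma(1, a), 1.0 / b], [1.0 / b, a / b**2]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:  # aψ'(a) -> 1 only as a -> inf
        raise EstimationError("singular information matrix") from exc
    se_log_a = np.sqrt(cov[0, 0]) / a
    se_log_b = np.sqrt(cov[1, 1]) / b
    ci_a = (a * np.exp(-_Z95 * se_log_a), a * np.exp(_Z95 * se_log_a))
    ci_b = (b * np.exp(-_Z95 * se_log_b), b * np.exp(_Z95 * se_log_b))
    return GammaEstimate(
        a=float(a),
        b=float(b),
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        n=int(n),
        dip_p=float(dip_p),
    )


def entry_signatures(
    entries: list[DataEntry],
    dip_alpha: float = DEFAULT_DIP_ALPHA,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[list[GammaEstimate], int]:
    """Dip-screen and Gamma-fit every entry, in acquisition order.

    Entries whose dip-test p-value falls below ``dip_alpha`` are discarded
    as multimodal contamination.  Zero magnitudes within a surviving entry
    are dropped before fitting (Gamma support is x > 0).  Returns the
    surviving estimates and the number of discarded entries; an empty
    result signals the participant should be excluded downstream.
    """
    estimates: list[GammaEstimate] = []
    discarded = 0
    n_zero = 0
    for entry in entries:
        dip, p = dip_test(entry.samples, n_boot=n_boot, seed=seed)
        if p < dip_alpha:
            discarded += 1
            continue
        positive = entry.samples[entry.samples > 0]
        n_zero += entry.samples.size - positive.size
        estimates.append(fit_gamma_mle(positive, dip_p=p))
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero magnitudes before fitting", stacklevel=2)
    if entries and not estimates:
        warnings.warn(
            "all entries discarded as multimodal; participant should be "
            "excluded from the cohort stage",
            stacklevel=2,
        )
    return estimates, discarded
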