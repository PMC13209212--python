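"""Interaction entropy, experimental-affinity conversion and trajectory statistics.

The entropy penalty is estimated by the interaction-entropy method
directly from the fluctuation of the inter-group interaction energy
E_MM(i) = dE_elec(i) + dE_vdW(i) along the trajectory:

    -T dS = k_B T ln < exp( dE_MM(i) / k_B T ) >,
    dE_MM(i) = E_MM(i) - <E_MM>.

The exponential average is evaluated with log-sum-exp so large
fluctuations cannot overflow.  By Jensen's inequality the result is
always >= 0 (an entropic penalty), and it is invariant under adding a
constant to the whole series.

Experimental binding free energies derive from inhibition constants via
dG_expr = -RT ln(1/K_i) = RT ln K_i (K_i in mol/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from . import constants
from .errors import EmptyInputError, InsufficientDataError, ValidationError


@dataclass
class FrameSeries:
    """Per-frame energy terms (kcal/mol); dh = e_mm + polar + nonpolar."""

    times: np.ndarray
    elec: np.ndarray
    vdw: np.ndarray
    polar: np.ndarray
    nonpolar: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(getattr(self, f), dtype=float)
            for f in ("times", "elec", "vdw", "polar", "nonpolar")
        ]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValidationError("all FrameSeries arrays must have equal length")
        self.times, self.elec, self.vdw, self.polar, self.nonpolar = arrays

    @property
    def e_mm(self) -> np.ndarray:
        return self.elec + self.vdw

    @property
    def dh(self) -> np.ndarray:
        return self.e_mm + self.polar + self.nonpolar

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Summary:
    """Trajectory means/SDs plus the entropy term and the assembled dG.

    Standard deviations accompany every averaged term; -T dS and dG are
    single trajectory-level numbers and carry no SD.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    minus_t_delta_s: float
    delta_g: float
    temperature: float


def interaction_entropy(e_mm_series, temperature: float) -> float:
    """-T dS in kcal/mol from the interaction-energy fluctuation series."""
    e = np.asarray(e_mm_series, dtype=float)
    if e.size < 2:
        raise InsufficientDataError(
            "interaction entropy needs at least 2 frames"
        )
    kbt = constants.BOLTZMANN_KCAL * temperature
    fluct = (e - e.mean()) / kbt
    # log <exp(x)> = logsumexp(x) - log N; stable for large fluctuations
    value = kbt * (logsumexp(fluct) - np.log(e.size))
    return max(float(value), 0.0)


def ki_to_dg(ki: float, temperature: float = 298.15) -> float:
    """dG_expr (kcal/mol) from an inhibition/dissociation constant in mol/L."""
    if ki <= 0:
        raise ValidationError("K_i must be positive")
    rt = constants.GAS_CONSTANT_KCAL * temperature
    return float(rt * np.log(ki))


_TERMS = ("dh", "e_mm", "polar", "nonpolar", "elec", "vdw")


def summarize(series: FrameSeries, temperature: float) -> Summary:
    """Means and sample (n-1) SDs per term; dG = mean(dH) + (-T dS)."""
    if len(series) == 0:
        raise EmptyInputError("cannot summarize an empty series")
    mean, sd = {}, {}
    for term in _TERMS:
        values = getattr(series, term)
        mean[term] = float(values.mean())
        sd[term] = float(values.std(ddof=1)) if len(series) > 1 else 0.0
    minus_tds = (
        interaction_entropy(series.e_mm, temperature) if len(series) > 1 else 0.0
    )
    return Summary(
        mean=mean,
        sd=sd,
        minus_t_delta_s=minus_tds,
        delta_g=mean["dh"] + minus_tds,
        temperature=temperature,
    )


def correlations(x, y) -> tuple[float, float, float]:
    """(Pearson r, Spearman r, Kendall tau-a).

    Pearson from centered products; Spearman from the rank-difference
    formula 1 - 6 sum d_i^2 / (n (n^2-1)) with average ranks for ties;
    Kendall tau-a = 2 (n_c - n_d) / (n (n-1)) from concordant/discordant
    pair counts with no tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("correlations need at least 3 observations")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = float((dx * dx).sum()), float((dy * dy).sum())
    if sxx == 0.0 or syy == 0.0:
        raise ValidationError("correlation undefined for zero-variance input")
    pearson = float((dx * dy).sum()) / np.sqrt(sxx * syy)

    d = rankdata(x) - rankdata(y)
    spearman = 1.0 - 6.0 * float((d * d).sum()) / (n * (n * n - 1))

    sign_x = np.sign(x[:, None] - x[None, :])
    sign_y = np.sign(y[:, None] - y[None, :])
    prod = sign_x * sign_y
    iu = np.triu_indices(n, k=1)
    n_c = int((prod[iu] > 0).sum())
    n_d = int((prod[iu] < 0).sum())
    tau = 2.0 * (n_c - n_d) / (n * (n - 1))
    return float(pearson), float(spearman), float(tau)
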