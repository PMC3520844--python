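"""Glycosyl-hydrolase specific activity from pNP-release kinetics.

Hydrolysis of a p-nitrophenyl glycoside releases p-nitrophenol (pNP),
whose absorbance grows linearly with product concentration (Beer-Lambert:
A = epsilon * l * c).  The absorbance time course is fit by ordinary least
squares; the slope in AU/min converts to a product formation rate and,
normalised by the protein mass in the assay, to a specific activity in
micromol pNP per minute per gram of protein.  One unit (U) is 1 micromol
of product per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import UndefinedRatioError

#: Measured molar absorption coefficient of pNP under assay conditions
#: (alkaline glycine buffer), in 1/(M*cm).
DEFAULT_EPSILON = 15_200.0

#: Default reaction volume in litres (50 microlitre microplate assay).
DEFAULT_VOLUME_L = 50e-6


@dataclass(frozen=True)
class AssayConfig:
    """Physical constants of one assay well.

    ``epsilon`` in 1/(M*cm); ``path_length`` in cm (microplate optical
    paths depend on fill volume, so there is no universal default);
    ``volume`` in litres; ``protein_mass`` in grams.
    """

    protein_mass: float
    path_length: float = 1.0
    epsilon: float = DEFAULT_EPSILON
    volume: float = DEFAULT_VOLUME_L
    substrate: str = ""

    def __post_init__(self) -> None:
        for name in ("protein_mass", "path_length", "epsilon", "volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class KineticsSeries:
    """Time course of absorbance: times in minutes, absorbance in AU."""

    times: tuple[float, ...]
    absorbances: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and absorbances must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "absorbances", tuple(float(x) for x in a))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ActivityResult:
    specific_activity: float  # micromol / min / g protein
    slope: float              # AU / min (blank-corrected)
    r_squared: float
    n_points: int
    clamped: bool = False     # True when a negative corrected slope was set to 0


def pnp_concentration(absorbance: float, config: AssayConfig) -> float:
    """pNP molar concentration from absorbance (Beer-Lambert)."""
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return absorbance / (config.epsilon * config.path_length)


def _ols_slope(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(t, a)
    return float(fit.slope), float(fit.rvalue ** 2), float(fit.stderr)


def _linear_prefix(t: np.ndarray, a: np.ndarray, min_r2: float) -> int:
    """Largest prefix length (>= 3 points) whose OLS fit has r^2 >= min_r2;
    falls back to the full series when no prefix qualifies."""
    best = len(t)
    for n in range(len(t), 2, -1):
        if _ols_slope(t[:n], a[:n])[1] >= min_r2:
            return n
    return best


def specific_activity(
    series: KineticsSeries,
    config: AssayConfig,
    blank: KineticsSeries | None = None,
    *,
    initial_linear_window: bool = False,
    min_r2: float = 0.98,
) -> ActivityResult:
    """Specific activity in micromol pNP per minute per gram of protein.

    The slope of the (optionally blank-corrected) absorbance series is fit
    by ordinary least squares over the full series; with
    ``initial_linear_window`` the fit is restricted to the largest initial
    stretch with r^2 >= ``min_r2``, guarding against substrate depletion in
    long incubations.  A decreasing corrected signal yields activity 0 with
    the ``clamped`` flag set.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points for a slope")
    t = np.asarray(series.times)
    a = np.asarray(series.absorbances, dtype=float)
    if blank is not None:
        a = a - np.interp(t, blank.times, blank.absorbances)
    n_used = len(t)
    if initial_linear_window and len(t) > 3:
        n_used = _linear_prefix(t, a, min_r2)
    slope, r2, _se = _ols_slope(t[:n_used], a[:n_used])
    clamped = slope < 0
    eff_slope = max(slope, 0.0)
    # AU/min -> M/min -> mol/min (times volume) -> umol/min -> per g protein
    rate_molar = eff_slope / (config.epsilon * config.path_length)
    umol_per_min = rate_molar * config.volume * 1e6
    activity = umol_per_min / config.protein_mass
    return ActivityResult(
        specific_activity=activity, slope=slope, r_squared=r2,
        n_points=n_used, clamped=clamped,
    )


def slope_standard_error(series: KineticsSeries,
                         blank: KineticsSeries | None = None) -> float:
    """Standard error of the OLS slope (AU/min), for recovery checks."""
    t = np.asarray(series.times)
    a = np.asarray(series.absorbances, dtype=float)
    if blank is not None:
        a = a - np.interp(t, blank.times, blank.absorbances)
    return _ols_slope(t, a)[2]


def fold_difference(a: ActivityResult | float, b: ActivityResult | float) -> float:
    """Ratio of two specific activities (a / b).

    A zero denominator — activity below the detection limit — makes the
    ratio undefined and raises rather than returning infinity.
    """
    av = a.specific_activity if isinstance(a, ActivityResult) else float(a)
    bv = b.specific_activity if isinstance(b, ActivityResult) else float(b)
    if bv <= 0:
        raise UndefinedRatioError("denominator activity is zero or negative")
    return av / bv


def read_kinetics_tsv(path) -> tuple[KineticsSeries, KineticsSeries | None]:
    """Read (time_min, absorbance[, blank_absorbance]) from a TSV file."""
    times: list[float] = []
    abso: list[float] = []
    blank: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not _is_float(fields[0]):
                continue  # header
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            times.append(float(fields[0]))
            abso.append(float(fields[1]))
            if len(fields) >= 3 and fields[2] not in ("", "."):
                blank.append(float(fields[2]))
    series = KineticsSeries(tuple(times), tuple(abso))
    blank_series = None
    if blank:
        if len(blank) != len(times):
            raise ValueError(f"{path}: blank column incomplete")
        blank_series = KineticsSeries(tuple(times), tuple(blank))
    return series, blank_series


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
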