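"""FTIR difference-spectrum unmixing and Meta-I <=> Meta-IIbH+ titration fits.

Each pH point of a difference-spectrum series is decomposed over reference
spectra of the two photoproduct states by non-negative least squares with a
sum-to-one constraint, over the 1800-1600 cm^-1 window (amide I plus the
protonated-carboxylic C=O region, the range most diagnostic of the
Meta-I/Meta-II transition).  The resulting Meta-IIbH+ fractions f(pH) are
fitted to a Henderson-Hasselbalch titration

    f(pH) = 1 / (1 + 10 ** (hill * (pH - pK))),

with the Hill slope fixed at 1 by default, yielding an apparent pK.  Mutant
series are classified against the wild type as forward-shifted,
Meta-I-stabilized, unaffected or complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "BasisSet",
    "TitrationFit",
    "MutantPhenotype",
    "decompose",
    "fit_titration",
    "classify_shift",
    "series_columns",
]

WINDOW = (1600.0, 1800.0)


@dataclass(frozen=True)
class BasisSet:
    """Named reference spectra on a common wavenumber grid."""

    wavenumbers: np.ndarray
    components: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        comps = {k: np.asarray(v, dtype=float) for k, v in self.components.items()}
        object.__setattr__(self, "components", comps)
        if len(comps) < 2:
            raise ValueError("basis needs >= 2 components")
        for name, y in comps.items():
            if y.shape != wn.shape:
                raise ValueError(f"component {name!r} not on the basis grid")

    @property
    def names(self) -> list[str]:
        return list(self.components)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.components[n] for n in self.names])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BasisSet":
        wn = df["wavenumber_cm-1"].to_numpy(dtype=float)
        comps = {c: df[c].to_numpy(dtype=float)
                 for c in df.columns if c != "wavenumber_cm-1"}
        return cls(wn, comps)


def series_columns(series: pd.DataFrame) -> list[tuple[float, str]]:
    """(pH value, column name) pairs of a spectrum-series frame, sorted by pH."""
    out = []
    for col in series.columns:
        if col.startswith("pH="):
            out.append((float(col[3:]), col))
    if not out:
        raise ValueError("series has no pH=<value> columns")
    return sorted(out)


def _constrained_fractions(B: np.ndarray, y: np.ndarray,
                           penalty: float = 1e4) -> tuple[np.ndarray, float]:
    """Non-negative coefficients summing to 1 minimizing ||B c - y||.

    The equality constraint is imposed as a heavily weighted augmented row
    on the NNLS system, then the coefficients are renormalized; exact for
    in-span mixtures.
    """
    scale = max(np.abs(B).max(), 1e-12)
    row = np.full((1, B.shape[1]), penalty * scale)
    A = np.vstack([B, row])
    b = np.concatenate([y, [penalty * scale]])
    c, _ = nnls(A, b)
    total = c.sum()
    if total > 0:
        c = c / total
    resid = float(np.linalg.norm(B @ c - y))
    return c, resid


def basis_from_extremes(series: pd.DataFrame) -> BasisSet:
    """Fallback basis: the most acidic and most alkaline spectra as proxies.

    When no reference spectra are available, the lowest-pH spectrum stands
    in for Meta-IIbH+ and the highest-pH spectrum for Meta-I.  The proxies
    inherit whatever residual contamination the endpoints carry, so
    fractions are compressed toward the endpoints' own mixing fractions;
    use measured reference spectra when possible.
    """
    cols = series_columns(series)
    wn = series["wavenumber_cm-1"].to_numpy(dtype=float)
    return BasisSet(wn, {
        "Meta-IIbH+": series[cols[0][1]].to_numpy(dtype=float),
        "Meta-I": series[cols[-1][1]].to_numpy(dtype=float),
    })


def decompose(series: pd.DataFrame, basis: BasisSet,
              window: tuple[float, float] = WINDOW,
              cond_limit: float = 1e8) -> pd.DataFrame:
    """Per-pH state fractions from constrained least-squares unmixing.

    Returns a DataFrame with one row per pH point, one fraction column per
    basis component (non-negative, summing to 1) and the per-pH residual
    norm.  Rejects series whose wavenumber grid does not match the basis,
    and degenerate bases (condition number above ``cond_limit``).
    """
    wn = series["wavenumber_cm-1"].to_numpy(dtype=float)
    if wn.shape != basis.wavenumbers.shape or not np.allclose(wn, basis.wavenumbers):
        raise ValueError("series wavenumber grid does not match the basis grid")
    mask = (wn >= window[0]) & (wn <= window[1])
    B = basis.matrix[mask]
    cond = float(np.linalg.cond(B))
    if cond > cond_limit:
        raise ValueError(f"degenerate basis (condition number {cond:.3g})")
    rows = []
    for pH, col in series_columns(series):
        y = series[col].to_numpy(dtype=float)[mask]
        c, resid = _constrained_fractions(B, y)
        row = {"pH": pH, "residual": resid}
        row.update({name: c[i] for i, name in enumerate(basis.names)})
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["condition_number"] = cond
    out.attrs["label"] = series.attrs.get("label", "")
    return out


@dataclass
class TitrationFit:
    """Apparent-pK fit of Meta-IIbH+ fraction vs pH."""

    pH: np.ndarray
    fractions: np.ndarray
    pK: float
    hill: float
    pK_stderr: float | None
    residual_norm: float
    max_residual: float
    two_state_ok: bool
    extrapolated: bool
    label: str = ""

    @property
    def alkaline_endpoint(self) -> float:
        """Observed Meta-IIbH+ fraction at the highest sampled pH."""
        return float(self.fractions[np.argmax(self.pH)])

    def to_json_dict(self) -> dict:
        return {
            "label": self.label, "pK": self.pK, "hill": self.hill,
            "pK_stderr": self.pK_stderr, "residual_norm": self.residual_norm,
            "max_residual": self.max_residual, "two_state_ok": self.two_state_ok,
            "extrapolated": self.extrapolated,
            "alkaline_endpoint": self.alkaline_endpoint,
            "pH": list(map(float, self.pH)),
            "fractions": list(map(float, self.fractions)),
        }


def logistic_fraction(pH, pK, hill=1.0):
    return 1.0 / (1.0 + 10.0 ** (hill * (np.asarray(pH, dtype=float) - pK)))


def fit_titration(pH, fractions, hill_fixed: bool = True,
                  residual_tolerance: float = 0.05,
                  label: str = "") -> TitrationFit:
    """Least-squares Henderson-Hasselbalch fit of fraction vs pH.

    Needs at least 4 pH points spanning 2 pH units and a non-flat fraction
    profile.  ``two_state_ok`` is true when the worst per-point residual is
    below ``residual_tolerance`` — a biphasic (multi-pK) profile fails this
    flag.  The fitted pK is flagged extrapolated when it falls more than one
    pH unit outside the sampled range.
    """
    p = np.asarray(pH, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if p.size < 4:
        raise ValueError("need >= 4 pH points")
    if p.max() - p.min() < 2.0:
        raise ValueError("pH points must span >= 2 pH units")
    if np.allclose(f, f[0]):
        raise ValueError("fractions show no transition in the sampled window")

    model = lmfit.Model(logistic_fraction, independent_vars=["pH"])
    params = model.make_params(pK=float(p[np.argmin(np.abs(f - 0.5))]), hill=1.0)
    params["hill"].set(vary=not hill_fixed, min=0.05)
    params["pK"].set(min=0.0, max=14.0)
    res = model.fit(f, params, pH=p)
    resid = res.best_fit - f
    pk = float(res.params["pK"].value)
    stderr = res.params["pK"].stderr
    return TitrationFit(
        pH=p, fractions=f, pK=pk, hill=float(res.params["hill"].value),
        pK_stderr=float(stderr) if stderr is not None else None,
        residual_norm=float(np.linalg.norm(resid)),
        max_residual=float(np.max(np.abs(resid))),
        two_state_ok=bool(np.max(np.abs(resid)) < residual_tolerance),
        extrapolated=not (p.min() - 1.0 <= pk <= p.max() + 1.0),
        label=label,
    )


def fit_series(series: pd.DataFrame, basis: BasisSet, hill_fixed: bool = True,
               metaii_component: str = "Meta-IIbH+") -> TitrationFit:
    """Convenience: decompose a spectrum series and fit the titration."""
    fr = decompose(series, basis)
    return fit_titration(fr["pH"].to_numpy(), fr[metaii_component].to_numpy(),
                         hill_fixed=hill_fixed,
                         label=series.attrs.get("label", ""))


@dataclass(frozen=True)
class MutantPhenotype:
    """Equilibrium-shift call for a mutant titration relative to wild type."""

    label: str  # forward_shifted | meta_I_stabilized | unaffected | complex
    delta_pK: float
    delta_plateau: float
    mutant_two_state_ok: bool

    def __post_init__(self) -> None:
        allowed = ("forward_shifted", "meta_I_stabilized", "unaffected", "complex")
        if self.label not in allowed:
            raise ValueError(f"label must be one of {allowed}")


def classify_shift(reference_fit: TitrationFit, mutant_fit: TitrationFit,
                   plateau_threshold: float = 0.2,
                   dpk_threshold: float = 0.3) -> MutantPhenotype:
    """Classify a mutant's Meta-I <=> Meta-II equilibrium shift.

    forward_shifted: the mutant retains an elevated Meta-II fraction at the
    alkaline endpoint (the equilibrium no longer titrates fully back to
    Meta-I), either outright (plateau excess > ``plateau_threshold``) or as
    a non-two-state curve with an elevated plateau.  meta_I_stabilized: the
    apparent pK drops by more than ``dpk_threshold``.  unaffected: pK and
    plateau both match.  Anything else is complex.
    """
    lo = max(reference_fit.pH.min(), mutant_fit.pH.min())
    hi = min(reference_fit.pH.max(), mutant_fit.pH.max())
    if hi <= lo:
        raise ValueError("titration pH ranges do not overlap")
    d_pk = mutant_fit.pK - reference_fit.pK
    d_plateau = mutant_fit.alkaline_endpoint - reference_fit.alkaline_endpoint

    if d_plateau > plateau_threshold or (
        not mutant_fit.two_state_ok and d_plateau > plateau_threshold / 2
    ):
        label = "forward_shifted"
    elif d_pk < -dpk_threshold:
        label = "meta_I_stabilized"
    elif abs(d_pk) <= dpk_threshold and abs(d_plateau) <= plateau_threshold \
            and mutant_fit.two_state_ok == reference_fit.two_state_ok:
        label = "unaffected"
    else:
        label = "complex"
    return MutantPhenotype(label=label, delta_pK=float(d_pk),
                           delta_plateau=float(d_plateau),
                           mutant_two_state_ok=mutant_fit.two_state_ok)
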