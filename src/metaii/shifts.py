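"""13C chemical-shift bookkeeping and interpretation.

Referencing conversions between TMS and DSS scales, per-site shift changes
between photostates (rhodopsin, Meta-I, Meta-II) against a reproducibility
threshold, and the serine-Cbeta hydrogen-bonding rule: the Ser 13Cbeta
resonance moves downfield when Cbeta-OH hydrogen bonding strengthens, so
the sign of a significant shift change reads out the direction of the
hydrogen-bonding change.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ShiftAssignment",
    "ShiftChange",
    "DSS_MINUS_TMS_PPM",
    "SIGNIFICANCE_PPM",
    "convert_reference",
    "state_delta",
    "classify_hbond_change",
]

#: 13C shift of DSS in D2O relative to neat TMS.
DSS_MINUS_TMS_PPM = 2.01

#: Run-to-run reproducibility of the reported shifts; smaller changes are
#: not interpreted.
SIGNIFICANCE_PPM = 0.2

STATES = ("rhodopsin", "Meta-I", "Meta-II")
REFERENCES = ("TMS", "DSS")


@dataclass(frozen=True)
class ShiftAssignment:
    """One assigned 13C resonance: site, photostate, shift and reference scale."""

    site: str
    state: str
    shift: float  # p.p.m.
    reference: str = "TMS"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.reference not in REFERENCES:
            raise ValueError(f"reference must be one of {REFERENCES}")
        if not (0.0 <= self.shift <= 250.0):
            raise ValueError("13C shift out of range [0, 250] p.p.m.")


@dataclass(frozen=True)
class ShiftChange:
    """Shift difference between two states at one site, with direction call."""

    site: str
    delta: float  # p.p.m., state2 - state1
    direction: str  # downfield | upfield | unchanged
    significance_threshold: float = SIGNIFICANCE_PPM

    def __post_init__(self) -> None:
        expect = _direction(self.delta, self.significance_threshold)
        if self.direction != expect:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with delta {self.delta}"
            )


def _direction(delta: float, threshold: float) -> str:
    if abs(delta) <= threshold:
        return "unchanged"
    return "downfield" if delta > 0 else "upfield"


def convert_reference(shift: float, from_ref: str, to_ref: str) -> float:
    """Convert a 13C shift between the TMS and DSS reference scales.

    TMS -> DSS adds 2.01 p.p.m.; the inverse subtracts it.
    """
    for ref in (from_ref, to_ref):
        if ref not in REFERENCES:
            raise ValueError(f"unknown reference {ref!r}; expected one of {REFERENCES}")
    if from_ref == to_ref:
        return shift
    return shift + DSS_MINUS_TMS_PPM if to_ref == "DSS" else shift - DSS_MINUS_TMS_PPM


def state_delta(a: ShiftAssignment, b: ShiftAssignment,
                threshold: float = SIGNIFICANCE_PPM) -> ShiftChange:
    """Shift change b - a for one site between two photostates."""
    if a.site != b.site:
        raise ValueError(f"sites differ: {a.site!r} vs {b.site!r}")
    if a.reference != b.reference:
        raise ValueError("mixed reference scales; convert_reference first")
    if a.state == b.state:
        raise ValueError("states must differ")
    delta = b.shift - a.shift
    return ShiftChange(site=a.site, delta=delta,
                       direction=_direction(delta, threshold),
                       significance_threshold=threshold)


def classify_hbond_change(change: ShiftChange) -> str:
    """Hydrogen-bond direction call for a serine Cbeta shift change.

    Returns 'increased', 'decreased' or 'unchanged'.  The rule is specific
    to Ser 13Cbeta sites (identified by a site label containing 'Ser' or
    'SER' and 'CB'/'Cbeta'); any other site is rejected.
    """
    site = change.site.upper().replace("Β", "B")
    if "SER" not in site or not ("CB" in site or "CBETA" in site):
        raise ValueError(
            f"hydrogen-bond rule applies only to Ser Cbeta sites, got {change.site!r}"
        )
    return {"downfield": "increased", "upfield": "decreased",
            "unchanged": "unchanged"}[change.direction]


def deltas_from_table(df: pd.DataFrame, state_a: str, state_b: str,
                      threshold: float = SIGNIFICANCE_PPM) -> pd.DataFrame:
    """Per-site shift changes from a long table (site, state, shift_ppm, reference).

    Sites present in both states are compared (after checking references
    match); returns a DataFrame with site, delta_ppm and direction.
    """
    rows = []
    for site, sub in df.groupby("site"):
        a = sub[sub["state"] == state_a]
        b = sub[sub["state"] == state_b]
        if a.empty or b.empty:
            continue
        sa = ShiftAssignment(site, state_a, float(a["shift_ppm"].iloc[0]),
                             str(a["reference"].iloc[0]))
        sb = ShiftAssignment(site, state_b, float(b["shift_ppm"].iloc[0]),
                             str(b["reference"].iloc[0]))
        ch = state_delta(sa, sb, threshold)
        rows.append({"site": site, "delta_ppm": ch.delta, "direction": ch.direction})
    return pd.DataFrame(rows, columns=["site", "delta_ppm", "direction"])
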