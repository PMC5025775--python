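"""Synthetic inputs with known ground truth.

Everything the analysis consumes can be generated here: DARR build-up
intensity tables with distance-dependent transfer and Gaussian noise, toy
coordinate files with atoms placed at prescribed pair distances, and
two-component FTIR difference-spectrum titration series mixed by a
Henderson-Hasselbalch law.  The generators exist for parameter-recovery
testing: every output carries its ground truth.

The default band positions of the synthetic Meta-I / Meta-IIbH+ reference
spectra are invented (documented constants): the two components differ in
an amide-I feature near 1644/1661 cm^-1 and in carboxylic C=O marker bands
in the 1700-1780 cm^-1 region.  Only the 1800-1600 cm^-1 decomposition
window and the 4 cm^-1 step are fixed by the experimental design being
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .buildup import (
    CALIBRATION_DISTANCES,
    DEFAULT_MIXING_GRID,
    BuildupParams,
    CrosspeakTable,
    simulate_buildup,
)

__all__ = [
    "GroundTruthGeometry",
    "NoiseModel",
    "TitrationGroundTruth",
    "DEFAULT_NOISE_RMS",
    "generate_buildup_dataset",
    "generate_toy_structure",
    "generate_titration_series",
    "default_basis",
    "calibration_geometry",
]

#: Default per-point Gaussian intensity noise (normalized units).  Chosen so
#: that (i) pairs beyond ~6.5 Å fall below the 3x-RMS detection threshold and
#: (ii) the Monte-Carlo spread of a 5.6 Å estimate is ~0.3 Å, the uncertainty
#: the signal-to-noise of the experiment supports.
DEFAULT_NOISE_RMS = 0.004


@dataclass(frozen=True)
class GroundTruthGeometry:
    """True pair distances, with internal-control pairs flagged.

    Control pairs sit at fixed intramolecular distances (retinal C5-C18 at
    1.4 Å, C8-C19 and C12-C20 at 2.4 Å, and the EL2 Cys/Gly backbone pairs)
    and anchor both normalization and rate calibration.
    """

    pairs: dict[str, float]
    control_pairs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("geometry must contain at least one pair")
        if any(d <= 0 for d in self.pairs.values()):
            raise ValueError("all distances must be positive")
        unknown = [p for p in self.control_pairs if p not in self.pairs]
        if unknown:
            raise ValueError(f"control pairs not in pairs: {unknown}")


def calibration_geometry() -> GroundTruthGeometry:
    """The five fixed-distance calibration pairs (1.4, 2.4, 3.6, 4.6, 5.3 Å)."""
    return GroundTruthGeometry(
        pairs=dict(CALIBRATION_DISTANCES),
        control_pairs=tuple(CALIBRATION_DISTANCES),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian intensity noise at a stated RMS."""

    noise_rms: float = DEFAULT_NOISE_RMS
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def generate_buildup_dataset(geometry: GroundTruthGeometry,
                             params: BuildupParams = BuildupParams(),
                             grid=DEFAULT_MIXING_GRID,
                             noise: NoiseModel = NoiseModel(noise_rms=0.0)) -> CrosspeakTable:
    """Simulate a crosspeak intensity table for every pair in the geometry.

    One intensity per (pair, mixing time, replicate); the noiseless values
    equal :func:`simulate_buildup` exactly and the noise is i.i.d. Gaussian
    with the stated RMS, reproducible under a fixed seed.
    """
    t = np.asarray(grid, dtype=float)
    if t.size == 0:
        raise ValueError("mixing-time grid must be non-empty")
    if np.any(t < 0):
        raise ValueError("mixing times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("mixing-time grid must be strictly increasing")

    rng = np.random.default_rng(noise.seed)
    rows = []
    for pair, r in geometry.pairs.items():
        clean = simulate_buildup(r, params, t)
        for rep in range(noise.replicate_count):
            eps = rng.normal(0.0, noise.noise_rms, t.shape) if noise.noise_rms > 0 else 0.0
            for ti, yi in zip(t, clean + eps):
                rows.append((pair, ti, rep, yi, noise.noise_rms))
    df = pd.DataFrame(rows, columns=CrosspeakTable.COLUMNS)
    return CrosspeakTable(df, normalized=False)


# ---------------------------------------------------------------------------
# toy coordinate models

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _parse_toy_selector(sel: str) -> tuple[str, int, str]:
    """'TYR268:CZ' -> ('TYR', 268, 'CZ'); 'RET:C20' -> ('RET', 1, 'C20')."""
    respart, _, atom = sel.partition(":")
    if not atom:
        raise ValueError(f"selector {sel!r} must be RESNUM:ATOM (e.g. TYR268:CZ)")
    name = respart.rstrip("0123456789")
    num = respart[len(name):]
    return name.upper(), int(num) if num else 1, atom.upper()


def _direction_sequence():
    """Deterministic sequence of well-spread unit vectors (golden spiral)."""
    i = 0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    while True:
        z = 1.0 - 2.0 * ((i % 64) + 0.5) / 64.0
        rad = np.sqrt(max(0.0, 1.0 - z * z))
        th = golden * i
        yield np.array([rad * np.cos(th), rad * np.sin(th), z])
        i += 1


def generate_toy_structure(spec: list[tuple[str, str, float]],
                           path=None) -> gemmi.Structure:
    """Place atoms so that every (selectorA, selectorB, distance) entry holds.

    Connected components of the selector graph are laid out 100 Å apart;
    within a component each new atom is placed along a fresh direction from
    its already-placed partner, so shared atoms (one selector in several
    pairs) are supported.  Entries that close a cycle are checked for
    consistency.  Standard residues become ATOM records, everything else
    (e.g. the retinal, residue name RET) HETATM.  If ``path`` is given the
    model is also written in PDB format.
    """
    if not spec:
        raise ValueError("empty placement spec")
    parsed = []
    for a, b, d in spec:
        if a == b:
            raise ValueError(f"duplicate atom selector in pair: {a!r}")
        if d <= 0:
            raise ValueError("target distances must be positive")
        parsed.append((_parse_toy_selector(a), _parse_toy_selector(b), float(d)))
    seen = set()
    for (sa, sb, _) in parsed:
        key = frozenset((sa, sb))
        if key in seen:
            raise ValueError(f"duplicate pair {sa}/{sb}")
        seen.add(key)

    # union of selectors; adjacency for placement
    atoms = sorted({s for sa, sb, _ in parsed for s in (sa, sb)})
    adj: dict[tuple, list[tuple]] = {a: [] for a in atoms}
    for sa, sb, d in parsed:
        adj[sa].append((sb, d))
        adj[sb].append((sa, d))

    pos: dict[tuple, np.ndarray] = {}
    dirs = _direction_sequence()
    comp_index = 0
    for root in atoms:
        if root in pos:
            continue
        origin = np.array([100.0 * comp_index, 0.0, 0.0])
        comp_index += 1
        pos[root] = origin
        stack = [root]
        while stack:
            cur = stack.pop()
            for nb, d in adj[cur]:
                if nb in pos:
                    continue
                pos[nb] = pos[cur] + d * next(dirs)
                stack.append(nb)
    for sa, sb, d in parsed:
        got = float(np.linalg.norm(pos[sa] - pos[sb]))
        if abs(got - d) > 1e-3:
            raise ValueError(
                f"constraints not realizable: {sa}-{sb} placed at {got:.3f} Å, wanted {d}"
            )

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    by_res: dict[tuple[str, int], list[tuple[str, np.ndarray]]] = {}
    for (name, num, atom) in atoms:
        by_res.setdefault((name, num), []).append((atom, pos[(name, num, atom)]))
    for (name, num) in sorted(by_res, key=lambda x: (x[1], x[0])):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(num, " ")
        res.het_flag = "A" if name in _AA3 else "H"
        for atom_name, p in sorted(by_res[(name, num)]):
            at = gemmi.Atom()
            at.name = atom_name
            at.element = gemmi.Element(atom_name[0])
            at.pos = gemmi.Position(*p)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if path is not None:
        st.write_pdb(str(path))
    return st


# ---------------------------------------------------------------------------
# titration spectrum series

@dataclass(frozen=True)
class TitrationGroundTruth:
    """Ground truth for a synthetic pH titration of the Meta-I <=> Meta-IIbH+ equilibrium.

    ``band_params`` lists (centre cm^-1, width cm^-1, amplitude, sign) tuples
    per component and is carried for provenance when a custom basis is built.
    """

    pK_true: float = 6.8
    hill_true: float = 1.0
    pH_grid: tuple[float, ...] = tuple(np.arange(4.5, 9.01, 0.5))
    band_params: tuple = ()

    def __post_init__(self) -> None:
        grid = np.asarray(self.pH_grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("pH grid must be strictly increasing with >= 2 points")
        if self.hill_true <= 0:
            raise ValueError("hill coefficient must be positive")
        for comp in self.band_params:
            for (centre, _w, _a, _s) in comp:
                if not (1600.0 <= centre <= 1800.0):
                    raise ValueError("band centres must lie within [1600, 1800] cm^-1")

    def fraction(self, pH) -> np.ndarray:
        """Meta-IIbH+ fraction f(pH) = 1 / (1 + 10**(hill*(pH - pK)))."""
        p = np.asarray(pH, dtype=float)
        return 1.0 / (1.0 + 10.0 ** (self.hill_true * (p - self.pK_true)))


#: wavenumber grid, descending 1800 -> 1600 cm^-1 at 4 cm^-1 resolution
DEFAULT_WAVENUMBERS = np.arange(1800.0, 1599.0, -4.0)

#: invented reference band sets (centre, width, amplitude) — difference-
#: spectrum features distinguishing the two photoproduct states
_META_I_BANDS = ((1663.0, 10.0, 0.60), (1637.0, 12.0, -0.80),
                 (1727.0, 9.0, -0.30), (1745.0, 9.0, 0.20))
_META_IIBH_BANDS = ((1644.0, 12.0, -1.00), (1661.0, 10.0, 0.30),
                    (1768.0, 8.0, 0.35), (1712.0, 10.0, -0.25))


def _gaussian_bands(wn: np.ndarray, bands) -> np.ndarray:
    y = np.zeros_like(wn)
    for centre, width, amp in bands:
        y += amp * np.exp(-0.5 * ((wn - centre) / width) ** 2)
    return y


def default_basis(wavenumbers: np.ndarray = DEFAULT_WAVENUMBERS) -> pd.DataFrame:
    """Synthetic Meta-I / Meta-IIbH+ reference difference spectra.

    Columns: wavenumber_cm-1, Meta-I, Meta-IIbH+.  The band constants are
    invented stand-ins for experimental reference spectra.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    return pd.DataFrame({
        "wavenumber_cm-1": wn,
        "Meta-I": _gaussian_bands(wn, _META_I_BANDS),
        "Meta-IIbH+": _gaussian_bands(wn, _META_IIBH_BANDS),
    })


def generate_titration_series(truth: TitrationGroundTruth,
                              basis: pd.DataFrame | None = None,
                              noise_rms: float = 0.0,
                              seed: int = 0,
                              label: str = "wild-type",
                              fraction_override=None) -> pd.DataFrame:
    """Mix the two basis spectra along a Henderson-Hasselbalch titration.

    Spectrum at pH p = f(p) * Meta-IIbH+ + (1 - f(p)) * Meta-I + noise, with
    f the (decreasing) logistic of the ground truth.  ``fraction_override``
    may supply an arbitrary f(pH) (e.g. a biphasic mutant curve).  Returns a
    DataFrame with a wavenumber column and one ``pH=<value>`` column per pH
    point; the sample label is stored in ``df.attrs['label']``.
    """
    if basis is None:
        basis = default_basis()
    required = {"wavenumber_cm-1", "Meta-I", "Meta-IIbH+"}
    if not required.issubset(basis.columns):
        raise ValueError(f"basis must have columns {sorted(required)}")
    grid = np.asarray(truth.pH_grid, dtype=float)
    if grid.min() < 3.0 or grid.max() > 10.0:
        raise ValueError("pH grid must lie within [3, 10]")
    wn = basis["wavenumber_cm-1"].to_numpy()
    frac_fn = fraction_override if fraction_override is not None else truth.fraction
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"wavenumber_cm-1": wn})
    for p in grid:
        f = float(frac_fn(p))
        y = f * basis["Meta-IIbH+"].to_numpy() + (1.0 - f) * basis["Meta-I"].to_numpy()
        if noise_rms > 0:
            y = y + rng.normal(0.0, noise_rms, wn.shape)
        out[f"pH={p:g}"] = y
    out.attrs["label"] = label
    out.attrs["pK_true"] = truth.pK_true
    return out
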