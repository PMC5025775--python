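"""Coordinate models, pocket distances and distance-restraint scoring.

Reads PDB-format coordinate models (gemmi behind the scenes), measures
specific atom-pair distances such as retinal-methyl to aromatic-carbon
separations, enumerates contacts under the DARR observability cutoff, and
scores candidate retinal orientations against NMR-derived restraint sets.

Selectors use PDB v3 atom naming: the tyrosine zeta carbon is CZ, the
glycine alpha carbon CA, a backbone carbonyl carbon C; the retinylidene
ligand is residue RET with atoms C1-C20.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .buildup import ABSENT_LIMIT, UPPER_LIMIT, DistanceEstimate

__all__ = [
    "AtomSelector",
    "CoordinateModel",
    "ContactPair",
    "Restraint",
    "RestraintSet",
    "ConsistencyScore",
    "read_structure",
    "pair_distance",
    "enumerate_contacts",
    "restraints_from_estimates",
    "score_model",
    "discriminate_models",
]

_RCSB_URL = "https://files.rcsb.org/download/{}.pdb"


@dataclass(frozen=True)
class AtomSelector:
    """Addresses one atom: optional chain, residue name and/or number, atom name.

    String form ``[CHAIN/]RES[NUM]:ATOM`` — e.g. ``A/TYR268:CZ``,
    ``RET:C20``, ``188:CA``.
    """

    atom: str
    res_name: str | None = None
    res_num: int | None = None
    chain: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        chain = None
        body = text.strip()
        if "/" in body:
            chain, body = body.split("/", 1)
        respart, sep, atom = body.partition(":")
        if not sep or not atom:
            raise ValueError(f"selector {text!r} must look like [CHAIN/]RES[NUM]:ATOM")
        name = respart.rstrip("0123456789")
        num = respart[len(name):]
        return cls(atom=atom.upper(), res_name=name.upper() or None,
                   res_num=int(num) if num else None, chain=chain or None)

    def __str__(self) -> str:
        res = f"{self.res_name or ''}{self.res_num if self.res_num is not None else ''}"
        return f"{self.chain + '/' if self.chain else ''}{res}:{self.atom}"


def _as_selector(sel) -> AtomSelector:
    return sel if isinstance(sel, AtomSelector) else AtomSelector.parse(str(sel))


class CoordinateModel:
    """A parsed structure restricted to one chain, with unique atom addressing."""

    def __init__(self, structure: gemmi.Structure, chain: str | None = None,
                 source: str = ""):
        if len(structure) == 0:
            raise ValueError("structure contains no models")
        self.structure = structure
        self.source = source or structure.name
        model = structure[0]
        names = [ch.name for ch in model]
        if not names:
            raise ValueError(f"{self.source}: structure has no chains")
        if chain is None:
            chain = self._first_protein_chain(model)
        if chain not in names:
            raise ValueError(
                f"{self.source}: chain {chain!r} not found; available chains: {names}"
            )
        self.chain_name = chain

    @staticmethod
    def _first_protein_chain(model: gemmi.Model) -> str:
        for ch in model:
            for res in ch:
                info = gemmi.find_tabulated_residue(res.name)
                if info is not None and info.is_amino_acid():
                    return ch.name
        return model[0].name

    @property
    def chain(self) -> gemmi.Chain:
        return self.structure[0][self.chain_name]

    def atoms_matching(self, sel: AtomSelector) -> list[tuple[gemmi.Residue, gemmi.Atom]]:
        chain = (self.structure[0][sel.chain] if sel.chain else self.chain)
        hits = []
        for res in chain:
            if sel.res_name is not None and res.name.upper() != sel.res_name:
                continue
            if sel.res_num is not None and res.seqid.num != sel.res_num:
                continue
            for atom in res:
                if atom.name.upper() == sel.atom:
                    hits.append((res, atom))
        return hits

    def resolve(self, sel) -> tuple[gemmi.Residue, gemmi.Atom]:
        sel = _as_selector(sel)
        hits = self.atoms_matching(sel)
        if not hits:
            raise KeyError(f"{self.source}: selector {sel} matches no atom "
                           f"in chain {sel.chain or self.chain_name}")
        if len(hits) > 1:
            labels = [f"{r.name}{r.seqid.num}:{a.name}" for r, a in hits]
            raise KeyError(f"{self.source}: selector {sel} is ambiguous: {labels}")
        return hits[0]

    def position(self, sel) -> np.ndarray:
        _, atom = self.resolve(sel)
        return np.array([atom.pos.x, atom.pos.y, atom.pos.z])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoordinateModel":
        """Rigid-body transformed copy (used to check scoring invariance)."""
        st = self.structure.clone()
        R = np.asarray(rotation, dtype=float)
        tvec = np.asarray(translation, dtype=float)
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        q = R @ p + tvec
                        atom.pos = gemmi.Position(*q)
        return CoordinateModel(st, chain=self.chain_name, source=self.source)


def read_structure(path_or_id, chain: str | None = None) -> CoordinateModel:
    """Read a PDB-format file, or fetch a 4-character PDB-ID from RCSB.

    HETATM records (including the retinal, residue name RET) are retained.
    Chain selection defaults to the first protein chain.  Fetching requires
    network access; a local file path always takes precedence.
    """
    text_id = str(path_or_id)
    p = Path(text_id)
    if p.exists():
        st = gemmi.read_structure(str(p), format=gemmi.CoorFormat.Detect)
        st.name = p.stem
        return CoordinateModel(st, chain=chain, source=str(p))
    if len(text_id) == 4 and text_id.isalnum():
        import urllib.request

        url = _RCSB_URL.format(text_id.upper())
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read().decode()
        except Exception as exc:  # pragma: no cover - needs network
            raise OSError(
                f"could not read {text_id!r}: no such file, and fetching {url} "
                f"failed ({exc})"
            ) from exc
        st = gemmi.read_pdb_string(data)
        st.name = text_id.upper()
        return CoordinateModel(st, chain=chain, source=text_id.upper())
    raise OSError(f"cannot read structure {text_id!r}: not a file or PDB-ID")


def pair_distance(model: CoordinateModel, sel_a, sel_b) -> float:
    """Euclidean distance (Å) between two addressed atom centres.

    Full precision is returned; round to 0.1 Å only when comparing with
    printed values.
    """
    return float(np.linalg.norm(model.position(sel_a) - model.position(sel_b)))


@dataclass(frozen=True)
class ContactPair:
    """One cross-class atom pair within the cutoff."""

    selector_a: str
    selector_b: str
    distance: float
    label: str = ""


def enumerate_contacts(model: CoordinateModel, class_a, class_b,
                       cutoff: float) -> list[ContactPair]:
    """All class-A vs class-B atom pairs within ``cutoff`` Å, sorted by distance.

    Class selectors may omit the residue number (e.g. ``TYR:CZ`` matches the
    zeta carbon of every tyrosine in the chain).  Pairs are deduplicated and
    self-pairs excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sa, sb = _as_selector(class_a), _as_selector(class_b)
    atoms_a = model.atoms_matching(sa)
    atoms_b = model.atoms_matching(sb)
    if not atoms_a or not atoms_b:
        warnings.warn("empty selector class; no contacts possible", stacklevel=2)
        return []
    out = []
    seen = set()
    for res_a, atom_a in atoms_a:
        pa = np.array([atom_a.pos.x, atom_a.pos.y, atom_a.pos.z])
        for res_b, atom_b in atoms_b:
            if res_a.seqid.num == res_b.seqid.num and res_a.name == res_b.name \
                    and atom_a.name == atom_b.name:
                continue
            key = frozenset(((res_a.name, res_a.seqid.num, atom_a.name),
                             (res_b.name, res_b.seqid.num, atom_b.name)))
            if key in seen:
                continue
            seen.add(key)
            pb = np.array([atom_b.pos.x, atom_b.pos.y, atom_b.pos.z])
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                out.append(ContactPair(
                    selector_a=f"{res_a.name}{res_a.seqid.num}:{atom_a.name}",
                    selector_b=f"{res_b.name}{res_b.seqid.num}:{atom_b.name}",
                    distance=d,
                    label=f"{res_a.name}{res_a.seqid.num}-{res_b.name}{res_b.seqid.num}",
                ))
    return sorted(out, key=lambda c: c.distance)


POSITIVE, UPPER, ABSENT = "POSITIVE", "UPPER", "ABSENT"


@dataclass(frozen=True)
class Restraint:
    """One distance restraint between two addressed atoms.

    POSITIVE: measured distance r +- sigma (crosspeak quantified).
    UPPER: distance <= limit (crosspeak observed but not quantified).
    ABSENT: distance >= limit (no crosspeak observed).
    """

    label: str
    kind: str
    selector_a: str
    selector_b: str
    r: float | None = None
    sigma: float | None = None
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.kind == POSITIVE:
            if self.r is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("POSITIVE restraint needs r and sigma > 0")
        elif self.kind in (UPPER, ABSENT):
            if self.limit is None or self.limit <= 0:
                raise ValueError(f"{self.kind} restraint needs a positive limit")
        else:
            raise ValueError(f"unknown restraint kind {self.kind!r}")


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"label": r.label, "type": r.kind, "selectorA": r.selector_a,
                 "selectorB": r.selector_b, "r": r.r, "sigma": r.sigma,
                 "limit": r.limit}
                for r in self.restraints
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RestraintSet":
        df = pd.read_csv(path, sep="\t")
        out = []
        for _, row in df.iterrows():
            def _f(v):
                return None if pd.isna(v) else float(v)
            out.append(Restraint(label=str(row["label"]), kind=str(row["type"]),
                                 selector_a=str(row["selectorA"]),
                                 selector_b=str(row["selectorB"]),
                                 r=_f(row["r"]), sigma=_f(row["sigma"]),
                                 limit=_f(row["limit"])))
        return cls(out)


def restraints_from_estimates(estimates: list[DistanceEstimate],
                              mapping: dict[str, tuple[str, str]]) -> RestraintSet:
    """Turn inverted distance estimates into a restraint set.

    ``mapping`` takes each crosspeak pair label to its (selectorA, selectorB)
    atom pair.  Quantified estimates become POSITIVE restraints; detected but
    unquantified crosspeaks become UPPER (<= 6.5 Å); absent crosspeaks become
    ABSENT (>= 6.0 Å).
    """
    out = []
    for est in estimates:
        if est.pair_label not in mapping:
            raise KeyError(f"no selector mapping for pair {est.pair_label!r}")
        sel_a, sel_b = mapping[est.pair_label]
        if est.status == "estimated":
            out.append(Restraint(label=est.pair_label, kind=POSITIVE,
                                 selector_a=sel_a, selector_b=sel_b,
                                 r=est.r_hat, sigma=est.sigma))
        elif est.status == "upper_bound_only":
            out.append(Restraint(label=est.pair_label, kind=UPPER,
                                 selector_a=sel_a, selector_b=sel_b,
                                 limit=UPPER_LIMIT))
        else:
            out.append(Restraint(label=est.pair_label, kind=ABSENT,
                                 selector_a=sel_a, selector_b=sel_b,
                                 limit=ABSENT_LIMIT))
    return RestraintSet(out)


@dataclass
class ConsistencyScore:
    """Restraint-satisfaction summary for one model."""

    model_id: str
    verdicts: list[dict]
    score: float
    violations: list[str]
    unevaluable: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"model_id": self.model_id, "score": self.score,
                "verdicts": self.verdicts, "violations": self.violations,
                "unevaluable": self.unevaluable}


def _violation_magnitude(restraint: Restraint, d: float) -> float:
    """Normalized magnitude of a violation (0 when satisfied)."""
    if restraint.kind == POSITIVE:
        return abs(d - restraint.r) / restraint.sigma
    if restraint.kind == UPPER:
        return max(0.0, d - restraint.limit) / restraint.limit
    return max(0.0, restraint.limit - d) / restraint.limit


def score_model(model: CoordinateModel, restraints: RestraintSet,
                tolerance_multiplier: float = 2.0) -> ConsistencyScore:
    """Fraction of restraints a model satisfies, with per-restraint verdicts.

    A POSITIVE restraint is satisfied when the model distance is within
    ``tolerance_multiplier`` standard deviations of the measured value;
    UPPER/ABSENT compare against their limits.  Restraints whose selectors
    do not resolve are marked unevaluable, excluded from the denominator
    and reported with a warning.
    """
    verdicts, violations, unevaluable = [], [], []
    n_sat = n_eval = 0
    for rs in restraints:
        try:
            d = pair_distance(model, rs.selector_a, rs.selector_b)
        except KeyError as exc:
            warnings.warn(f"restraint {rs.label}: {exc}", stacklevel=2)
            unevaluable.append(rs.label)
            verdicts.append({"label": rs.label, "kind": rs.kind,
                             "distance": None, "satisfied": None})
            continue
        if rs.kind == POSITIVE:
            ok = abs(d - rs.r) <= tolerance_multiplier * rs.sigma
        elif rs.kind == UPPER:
            ok = d <= rs.limit
        else:
            ok = d >= rs.limit
        n_eval += 1
        n_sat += ok
        if not ok:
            violations.append(rs.label)
        verdicts.append({"label": rs.label, "kind": rs.kind, "distance": d,
                         "satisfied": bool(ok),
                         "violation": _violation_magnitude(rs, d) if not ok else 0.0})
    score = n_sat / n_eval if n_eval else 0.0
    return ConsistencyScore(model_id=model.source, verdicts=verdicts,
                            score=score, violations=violations,
                            unevaluable=unevaluable)


def discriminate_models(models: dict[str, CoordinateModel],
                        restraints: RestraintSet,
                        tolerance_multiplier: float = 2.0) -> dict:
    """Rank candidate models by restraint-satisfaction score.

    Ties on score are broken by the summed normalized violation magnitude
    (smaller wins); models still tied after that are reported as ties.
    Returns a dict with the ordered ranking, per-model scores and the full
    per-restraint table.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to discriminate")
    scored = {}
    keys = {}
    for name, model in models.items():
        sc = score_model(model, restraints, tolerance_multiplier)
        total_viol = sum(v.get("violation", 0.0) or 0.0 for v in sc.verdicts)
        scored[name] = sc
        keys[name] = (-sc.score, total_viol)
    order = sorted(models, key=lambda n: keys[n])
    ties = [
        [a, b] for i, a in enumerate(order) for b in order[i + 1:]
        if keys[a] == keys[b]
    ]
    return {
        "ranking": order,
        "best": order[0],
        "ties": ties,
        "scores": {n: scored[n].to_json_dict() for n in scored},
    }


def scores_to_json(result: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2)
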