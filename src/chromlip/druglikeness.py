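"""Rule-based drug-likeness screening.

Threshold filters on simple molecular descriptors that flag whether a
molecule resembles known oral drugs:

* Lipinski's rule of five — MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10; a
  molecule fails only when it violates two or more of the four conditions.
* Ghose — AlogP in [−0.4, 5.6], MW in [160, 480], molar refractivity in
  [40, 130], heavy-atom count in [20, 70]; all must hold.
* Veber — rotatable bonds ≤ 10 and TPSA ≤ 140 Å².
* Egan — TPSA ≤ 131.6 Å² and AlogP98 ≤ 5.88 (the published model bounds).
* Muegge — a multi-descriptor pharmacophore-point filter; the conditions
  evaluable from this package's descriptor tables are MW in [200, 600],
  XLOGP in [−2, 5], TPSA ≤ 150, rotatable bonds ≤ 15, HBA ≤ 10, HBD ≤ 5.

All range bounds are inclusive (a documented convention; the prose sources
are ambiguous). Each verdict records, per condition, whether its threshold
was stated numerically by the study that this package reproduces
("study") or taken from the rule's original publication
("external-default").
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import DescriptorLookupError

__all__ = [
    "Violation",
    "RuleVerdict",
    "lipinski",
    "ghose",
    "veber",
    "egan",
    "muegge",
    "verdict_grid",
]


@dataclass(frozen=True)
class Violation:
    condition: str
    observed: float
    bound: float


@dataclass(frozen=True)
class RuleVerdict:
    rule: str
    passed: bool
    violations: tuple[Violation, ...]
    thresholds_provenance: Mapping[str, str] = field(default_factory=dict)


def _get(d, name: str) -> float:
    try:
        v = d[name]
    except (KeyError, IndexError, TypeError) as exc:
        raise DescriptorLookupError(f"descriptor field {name!r} is missing") from exc
    if pd.isna(v):
        raise DescriptorLookupError(f"descriptor field {name!r} is missing (NaN)")
    return float(v)


def lipinski(d, logp: float) -> RuleVerdict:
    """Rule of five; fails only on two or more violated conditions.

    ``logp`` is caller-supplied; the conventional source for the screen
    reproduced here is the MLOGP column of the prediction matrix.
    """
    mw, hbd, hba = _get(d, "molar_mass"), _get(d, "hbd"), _get(d, "hba")
    checks = [("MW>500", mw, 500.0), ("logP>5", float(logp), 5.0),
              ("HBD>5", hbd, 5.0), ("HBA>10", hba, 10.0)]
    violations = tuple(
        Violation(c, obs, bound) for c, obs, bound in checks if obs > bound
    )
    prov = {c: "study" for c, _, _ in checks}
    return RuleVerdict("lipinski", len(violations) < 2, violations, prov)


def ghose(d, alogp: float, mr: float, atoms: float) -> RuleVerdict:
    """Ghose qualifying ranges; every condition must hold.

    ``mr`` is caller-supplied because molar refractivity differs between
    computation programs enough to flip the verdict near the 130 bound.
    """
    mw = _get(d, "molar_mass")
    checks = [
        ("AlogP<-0.4", float(alogp), -0.4, "lo"),
        ("AlogP>5.6", float(alogp), 5.6, "hi"),
        ("MW<160", mw, 160.0, "lo"),
        ("MW>480", mw, 480.0, "hi"),
        ("MR<40", float(mr), 40.0, "lo"),
        ("MR>130", float(mr), 130.0, "hi"),
        ("atoms<20", float(atoms), 20.0, "lo"),
        ("atoms>70", float(atoms), 70.0, "hi"),
    ]
    violations = tuple(
        Violation(c, obs, bound)
        for c, obs, bound, side in checks
        if (obs < bound if side == "lo" else obs > bound)
    )
    prov = {c: "study" for c, _, _, _ in checks}
    return RuleVerdict("ghose", not violations, violations, prov)


def veber(d) -> RuleVerdict:
    """Veber oral-bioavailability filter: ≤10 rotatable bonds, TPSA ≤ 140 Å²."""
    rot, tpsa = _get(d, "rotatable_bonds"), _get(d, "tpsa")
    checks = [("RotB>10", rot, 10.0), ("TPSA>140", tpsa, 140.0)]
    violations = tuple(
        Violation(c, obs, bound) for c, obs, bound in checks if obs > bound
    )
    prov = {c: "study" for c, _, _ in checks}
    return RuleVerdict("veber", not violations, violations, prov)


#: Egan model bounds from its original publication.
EGAN_DEFAULTS = {"TPSA": 131.6, "AlogP98": 5.88}

#: Muegge thresholds other than the XLOGP upper bound, from its publication.
MUEGGE_DEFAULTS = {
    "MW_lo": 200.0,
    "MW_hi": 600.0,
    "XLOGP_lo": -2.0,
    "XLOGP_hi": 5.0,
    "TPSA": 150.0,
    "RotB": 15.0,
    "HBA": 10.0,
    "HBD": 5.0,
}


def egan(d, alogp98: float, thresholds: Mapping[str, float] | None = None) -> RuleVerdict:
    t = dict(EGAN_DEFAULTS, **(thresholds or {}))
    tpsa = _get(d, "tpsa")
    checks = [("TPSA>131.6", tpsa, t["TPSA"]), ("AlogP98>5.88", float(alogp98), t["AlogP98"])]
    violations = tuple(
        Violation(c, obs, bound) for c, obs, bound in checks if obs > bound
    )
    prov = {c: "external-default" for c, _, _ in checks}
    return RuleVerdict("egan", not violations, violations, prov)


def muegge(d, xlogp3: float, thresholds: Mapping[str, float] | None = None) -> RuleVerdict:
    """Muegge filter over the descriptor fields this package carries.

    Only the XLOGP ≤ 5 upper bound is stated by the reproduced study itself;
    every other threshold comes from the rule's publication.
    """
    t = dict(MUEGGE_DEFAULTS, **(thresholds or {}))
    mw = _get(d, "molar_mass")
    tpsa = _get(d, "tpsa")
    rot = _get(d, "rotatable_bonds")
    hba, hbd = _get(d, "hba"), _get(d, "hbd")
    x = float(xlogp3)
    checks = [
        ("MW<200", mw, t["MW_lo"], "lo"),
        ("MW>600", mw, t["MW_hi"], "hi"),
        ("XLOGP3<-2", x, t["XLOGP_lo"], "lo"),
        ("XLOGP3>5", x, t["XLOGP_hi"], "hi"),
        ("TPSA>150", tpsa, t["TPSA"], "hi"),
        ("RotB>15", rot, t["RotB"], "hi"),
        ("HBA>10", hba, t["HBA"], "hi"),
        ("HBD>5", hbd, t["HBD"], "hi"),
    ]
    violations = tuple(
        Violation(c, obs, bound)
        for c, obs, bound, side in checks
        if (obs < bound if side == "lo" else obs > bound)
    )
    prov = {c: ("study" if c == "XLOGP3>5" else "external-default")
            for c, _, _, _ in checks}
    return RuleVerdict("muegge", not violations, violations, prov)


def _cell(verdict: RuleVerdict) -> str:
    if verdict.passed:
        return "+"
    return "-(" + ";".join(v.condition for v in verdict.violations) + ")"


def verdict_grid(
    descriptors: pd.DataFrame,
    logp_matrix,
    mr_source: str = "swissadme",
) -> pd.DataFrame:
    """Rules × compounds grid of "+" / "-(condition)" cells.

    ``descriptors`` is indexed by compound id with the DescriptorTable
    fields; ``logp_matrix`` supplies MLOGP (Lipinski), WLOGP (Ghose/Egan) and
    XLOGP3 (Muegge). ``mr_source`` picks the molar-refractivity column:
    ``"swissadme"`` (the screen's own provenance; the bundled values are
    synthetic stand-ins above/below the 130 bound) or ``"chem3d"`` (the
    published descriptor table).
    """
    mr_col = {"swissadme": "mr_swissadme_synthetic", "chem3d": "molar_refractivity"}
    if mr_source not in mr_col:
        raise ValueError(f"mr_source must be one of {sorted(mr_col)}")
    grid = {}
    lp = logp_matrix.frame
    for cid in descriptors.index:
        d = descriptors.loc[cid]
        grid[cid] = {
            "lipinski": _cell(lipinski(d, logp=lp.loc[cid, "MLOGP"])),
            "ghose": _cell(
                ghose(d, alogp=lp.loc[cid, "WLOGP"], mr=d[mr_col[mr_source]],
                      atoms=d["heavy_atoms"])
            ),
            "veber": _cell(veber(d)),
            "egan": _cell(egan(d, alogp98=lp.loc[cid, "WLOGP"])),
            "muegge": _cell(muegge(d, xlogp3=lp.loc[cid, "XLOGP3"])),
        }
    out = pd.DataFrame(grid)
    out.index.name = "rule"
    out.columns.name = "compound_id"
    return out
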