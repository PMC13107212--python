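"""Yields, enantiomer ratios and effective free-energy gaps.

The enantiomer ratio (er) of a kinetic simulation is read from the final
populations of the S- and R-product groups; the effective gap between the
competing channels follows from ΔΔG‡ = R·T·ln(major/minor).  The
conventional Boltzmann-weighted TS-ensemble estimate is provided as the
Curtin–Hammett baseline the network simulation generalizes: the two agree
when reactant conformers pre-equilibrate and product formation is
irreversible, and part ways once reverse (racemizing) steps matter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import rt_kj
from .kinetics import KineticState

__all__ = [
    "SelectivityResult",
    "ddg_from_ratio",
    "ratio_from_ddg",
    "boltzmann_ts_ensemble_ratio",
    "aggregate_yields",
    "ee_from_er",
]


def ddg_from_ratio(ratio: float, temperature: float) -> float:
    """Free-energy gap ΔΔG = R·T·ln(ratio) in kJ/mol for a rate/population ratio."""
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return rt_kj(temperature) * math.log(ratio)


def ratio_from_ddg(ddg: float, temperature: float) -> float:
    """Inverse of :func:`ddg_from_ratio`: ratio = exp(ΔΔG/RT)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return math.exp(ddg / rt_kj(temperature))


def ee_from_er(fraction_major: float, fraction_minor: float) -> float:
    """Enantiomeric excess in % from the two er fractions (ee = |S−R|)."""
    return abs(fraction_major - fraction_minor)


def boltzmann_ts_ensemble_ratio(
    ts_energies_s: Iterable[float],
    ts_energies_r: Iterable[float],
    temperature: float,
) -> float:
    """S:R rate ratio from Boltzmann-weighted TS ensembles.

    ratio = Σ exp(−g/RT) over S-forming TSs / Σ over R-forming TSs.  This is
    the conventional single-step selectivity estimate, exact in the
    Curtin–Hammett regime.
    """
    gs = np.asarray(list(ts_energies_s), dtype=float)
    gr = np.asarray(list(ts_energies_r), dtype=float)
    if gs.size == 0 or gr.size == 0:
        raise ValueError("both TS energy lists must be nonempty")
    rt = rt_kj(temperature)
    ref = min(gs.min(), gr.min())
    return float(
        np.exp(-(gs - ref) / rt).sum() / np.exp(-(gr - ref) / rt).sum()
    )


@dataclass
class SelectivityResult:
    """Yield, enantiomer ratio and effective ΔΔG‡ of a simulation endpoint.

    ``fraction_s``/``fraction_r`` are percentages of the *product* population
    (summing to 100); they are ``None`` when no product has formed, in which
    case the er is undefined rather than 50:50.
    """

    yield_total: float
    fraction_s: float | None
    fraction_r: float | None
    ddg_effective: float | None
    temperature: float

    @property
    def er_text(self) -> str:
        if self.fraction_s is None:
            return "undefined"
        return f"{self.fraction_s:.2f}:{self.fraction_r:.2f}"

    def to_dict(self) -> dict:
        return {
            "yield_percent": self.yield_total,
            "fraction_S_percent": self.fraction_s,
            "fraction_R_percent": self.fraction_r,
            "er": self.er_text,
            "ddg_effective_kjmol": self.ddg_effective,
            "temperature_K": self.temperature,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def __str__(self) -> str:
        ddg = "n/a" if self.ddg_effective is None else f"{self.ddg_effective:.2f} kJ/mol"
        return (
            f"yield {self.yield_total:.2f}%  er(S:R) {self.er_text}  "
            f"ddG‡ {ddg}  T {self.temperature:.2f} K"
        )


def aggregate_yields(
    final: KineticState,
    node_to_group: Mapping[str, str],
    product_groups_s: Iterable[str],
    product_groups_r: Iterable[str],
    temperature: float,
) -> SelectivityResult:
    """Fold final node populations into yield, er and effective ΔΔG‡.

    All product groups of a given handedness (e.g. differently protonated
    product species) sum into one enantiomer fraction.  The S and R group
    sets must be disjoint.
    """
    s_set, r_set = set(product_groups_s), set(product_groups_r)
    if s_set & r_set:
        raise ValueError(f"S and R group sets overlap: {sorted(s_set & r_set)}")
    pop_s = pop_r = 0.0
    for nid, p in zip(final.node_order, final.populations):
        grp = node_to_group.get(nid)
        if grp in s_set:
            pop_s += p
        elif grp in r_set:
            pop_r += p
    total = pop_s + pop_r
    yield_total = 100.0 * total
    if total <= 0.0:
        return SelectivityResult(yield_total, None, None, None, temperature)
    frac_s = 100.0 * pop_s / total
    frac_r = 100.0 - frac_s
    major, minor = max(pop_s, pop_r), min(pop_s, pop_r)
    ddg = math.inf if minor == 0.0 else ddg_from_ratio(major / minor, temperature)
    return SelectivityResult(yield_total, frac_s, frac_r, ddg, temperature)
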