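"""Fecal diet tabulation and the contribution-to-DCB statistic.

Scat contents of free-ranging cats are tabulated as frequency of occurrence
(FO, percent of scats containing an item at least once) and minimum number of
individuals (NI, tallied from diagnostic bones).  Each prey taxon's share of
the cats' energy budget is then scored by the contribution statistic

    contribution = 100 * (prey body weight * NI / n_scats) / mean DCB

where DCB is the daily consumed biomass predicted allometrically from the
predator's body weight, one defecation per day is assumed, and prey heavier
than the heaviest cat's DCB are capped at that maximum (a cat abandons what
it cannot eat in a day).  Taxa whose contribution exceeds a threshold
(default 3%) become the candidate sources for the isotope mixing model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HABITATS",
    "GROUPS",
    "PreyTaxon",
    "ScatRecord",
    "CatRecord",
    "ContributionTable",
    "daily_consumed_biomass",
    "mean_dcb",
    "frequency_of_occurrence",
    "contribution_to_dcb",
    "category_contributions",
    "select_sources",
    "fisher_group_test",
    "round1",
]

HABITATS = ("forest", "farmland", "unknown", "artificial", "plant")
GROUPS = ("feral", "stray", "indoor", "sheltered")

# DCB = 3.358 * W^0.813 * 2.86/18 with W in grams: 2.86 rescales dry prey
# mass for 65% water content, 18 kJ/g is the metabolizable energy density.
_DCB_COEF = 3.358
_DCB_EXP = 0.813
_DCB_WATER = 2.86
_DCB_ENERGY = 18.0


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class TaxonResolutionError(KeyError):
    """Raised when scat items reference taxa missing from the taxon table."""

    def __init__(self, offenders: Sequence[str]):
        self.offenders = sorted(set(offenders))
        super().__init__(f"unresolvable taxa: {', '.join(self.offenders)}")


class ConfigurationError(ValueError):
    """Raised when a countable taxon lacks the body weight Eq-style scoring needs."""


@dataclass(frozen=True)
class PreyTaxon:
    """A prey taxon with its habitat category and mean body weight in grams."""

    name: str
    habitat: str
    mean_body_weight: float | None = None  # grams
    conservation_status: str | None = None

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise InvalidInputError(
                f"{self.name}: habitat {self.habitat!r} not in {HABITATS}"
            )
        if self.mean_body_weight is not None and not self.mean_body_weight > 0:
            raise InvalidInputError(f"{self.name}: body weight must be positive")


@dataclass(frozen=True)
class ScatRecord:
    """One scat's identified items as (taxon name, minimum individual count)."""

    scat_id: str
    cat_id: str
    items: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        for name, count in self.items:
            if not (isinstance(count, (int, np.integer)) and count >= 0):
                raise InvalidInputError(
                    f"scat {self.scat_id}: count for {name} must be a non-negative integer"
                )


@dataclass(frozen=True)
class CatRecord:
    """Capture metadata for one cat; weight is accepted in kg, stored in g."""

    cat_id: str
    group: str
    sex: str = "unknown"
    weight_g: float | None = None
    ear_tipped: bool | None = None
    capture_xy: tuple[float, float] | None = None
    capture_date: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidInputError(f"{self.cat_id}: group {self.group!r} not in {GROUPS}")
        if self.sex not in ("female", "male", "unknown"):
            raise InvalidInputError(f"{self.cat_id}: sex {self.sex!r}")
        if self.weight_g is not None and not self.weight_g > 0:
            raise InvalidInputError(f"{self.cat_id}: weight must be positive")

    @classmethod
    def from_kg(cls, cat_id, group, weight_kg=None, **kw):
        wg = None if weight_kg is None else float(weight_kg) * 1000.0
        return cls(cat_id=cat_id, group=group, weight_g=wg, **kw)


@dataclass
class ContributionTable:
    """Per-taxon FO/NI/contribution rows plus per-category subtotals.

    ``taxon_rows`` and ``category_rows`` hold unrounded values; rounding is a
    display concern (`format`).  ``contribution_percent`` is NaN for taxa
    without a body weight (insects pooled as unknown, artificial objects,
    plants), which are tabulated for FO/NI only.
    """

    taxon_rows: pd.DataFrame
    category_rows: pd.DataFrame
    n_scats: int
    mean_dcb: float
    max_dcb: float

    def format(self, decimals: int = 1) -> pd.DataFrame:
        out = self.taxon_rows.copy()
        for c in out.columns:
            if c.startswith(("FO_", "contribution")):
                out[c] = out[c].map(lambda v: float(round1(v, decimals)) if np.isfinite(v) else v)
        return out


def round1(x: float, decimals: int = 1) -> float:
    """Round half-up to ``decimals`` places (display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Allometric daily consumed biomass
# ---------------------------------------------------------------------------

def daily_consumed_biomass(weight_kg: float) -> float:
    """Daily consumed biomass (g wet prey/day) of a predator of ``weight_kg``.

    Evaluates 3.358 * W_g**0.813 * 2.86/18 with the predator weight converted
    to grams.  Returns the unrounded value; printed tables truncate to whole
    grams (`dcb_grams`).
    """
    if not (np.isfinite(weight_kg) and weight_kg > 0):
        raise InvalidInputError(f"predator weight must be positive, got {weight_kg!r}")
    w_g = float(weight_kg) * 1000.0
    return _DCB_COEF * w_g**_DCB_EXP * _DCB_WATER / _DCB_ENERGY


def dcb_grams(weight_kg: float) -> int:
    """`daily_consumed_biomass` truncated to whole grams, as printed."""
    return int(math.floor(daily_consumed_biomass(weight_kg)))


def mean_dcb(cats: Iterable[CatRecord | float]) -> dict:
    """Mean ± SD (and range) of per-cat DCB.

    DCB is computed per cat and then averaged; because the allometry is a
    concave power of weight this differs from the DCB of the mean weight.
    Accepts `CatRecord`s (cats without a recorded weight are skipped) or bare
    weights in kilograms.
    """
    weights = []
    for c in cats:
        if isinstance(c, CatRecord):
            if c.weight_g is not None:
                weights.append(c.weight_g / 1000.0)
        else:
            weights.append(float(c))
    if not weights:
        raise InvalidInputError("no cats with recorded weight")
    dcb = np.array([daily_consumed_biomass(w) for w in weights])
    return {
        "mean": float(dcb.mean()),
        "sd": float(dcb.std(ddof=1)) if len(dcb) > 1 else 0.0,
        "min": float(dcb.min()),
        "max": float(dcb.max()),
        "n": len(dcb),
    }


# ---------------------------------------------------------------------------
# Frequency of occurrence
# ---------------------------------------------------------------------------

def _resolve(selector: str, taxa: dict[str, PreyTaxon]) -> set[str]:
    """Selector is a taxon name or a habitat category; return matching names."""
    if selector in taxa:
        return {selector}
    if selector in HABITATS:
        return {t.name for t in taxa.values() if t.habitat == selector}
    raise TaxonResolutionError([selector])


def _check_items(scats: Sequence[ScatRecord], taxa: dict[str, PreyTaxon]):
    offenders = [n for s in scats for n, _ in s.items if n not in taxa]
    if offenders:
        raise TaxonResolutionError(offenders)


def frequency_of_occurrence(
    scats: Sequence[ScatRecord],
    taxa: Sequence[PreyTaxon] | dict[str, PreyTaxon],
    selector: str,
    cats: Sequence[CatRecord] | None = None,
) -> dict[str, float]:
    """FO (%) of ``selector`` (taxon name or habitat category) per group and total.

    A scat counts once regardless of how many matching items it holds.  Group
    membership comes from ``cats``; with no cats given a single "total" figure
    is returned.
    """
    taxa = taxa if isinstance(taxa, dict) else {t.name: t for t in taxa}
    _check_items(scats, taxa)
    match = _resolve(selector, taxa)
    group_of = {c.cat_id: c.group for c in cats} if cats else {}

    def _fo(sub: Sequence[ScatRecord]) -> float:
        if not sub:
            return float("nan")
        hit = sum(
            1 for s in sub if any(n in match and c >= 1 for n, c in s.items)
        )
        return 100.0 * hit / len(sub)

    out = {"total": _fo(scats)}
    if cats:
        for g in dict.fromkeys(group_of.values()):
            out[g] = _fo([s for s in scats if group_of.get(s.cat_id) == g])
    return out


# ---------------------------------------------------------------------------
# Contribution to DCB (the source-selection statistic)
# ---------------------------------------------------------------------------

def contribution_to_dcb(
    taxon: PreyTaxon,
    ni: int,
    n_scats: int,
    mean_dcb: float,
    max_dcb: float = math.inf,
) -> float:
    """Percent of mean daily consumed biomass attributed to ``taxon``.

    The taxon's mean body weight is capped at ``max_dcb`` (prey heavier than
    a day's intake are only partly eaten).  One scat per cat-day is assumed,
    so NI/n_scats is prey individuals per cat-day.
    """
    if not n_scats > 0:
        raise InvalidInputError("n_scats must be positive")
    if not mean_dcb > 0:
        raise InvalidInputError("mean_dcb must be positive")
    if ni < 0:
        raise InvalidInputError("NI must be non-negative")
    if taxon.mean_body_weight is None:
        raise ConfigurationError(
            f"{taxon.name}: body weight required to compute a contribution"
        )
    w_eff = min(taxon.mean_body_weight, max_dcb)
    return 100.0 * (w_eff * ni / n_scats) / mean_dcb


def category_contributions(
    taxa: Sequence[PreyTaxon],
    ni_by_taxon: dict[str, dict[str, int] | int],
    n_scats: int,
    mean_dcb: float,
    max_dcb: float = math.inf,
    scats: Sequence[ScatRecord] | None = None,
    cats: Sequence[CatRecord] | None = None,
) -> ContributionTable:
    """Build the full contribution table with per-category subtotals.

    ``ni_by_taxon`` maps taxon name to NI, either a plain total or a
    ``{group: NI}`` dict (summed for the total).  When ``scats`` are given,
    per-taxon and per-category FO columns are added.  Category subtotals sum
    the unrounded member contributions; taxa without body weight contribute
    NaN and are excluded from subtotals.
    """
    taxa = list(taxa)
    tmap = {t.name: t for t in taxa}
    rows = []
    for t in taxa:
        ni = ni_by_taxon.get(t.name, 0)
        ni_total = sum(ni.values()) if isinstance(ni, dict) else int(ni)
        if t.mean_body_weight is None:
            contrib = float("nan")
        else:
            contrib = contribution_to_dcb(t, ni_total, n_scats, mean_dcb, max_dcb)
        row = {
            "taxon": t.name,
            "habitat": t.habitat,
            "body_weight_g": t.mean_body_weight,
            "NI_total": ni_total,
            "contribution_percent": contrib,
        }
        if isinstance(ni, dict):
            for g, v in ni.items():
                row[f"NI_{g}"] = int(v)
        if scats is not None:
            fo = frequency_of_occurrence(scats, tmap, t.name, cats)
            for g, v in fo.items():
                row[f"FO_{g}"] = v
        rows.append(row)
    taxon_rows = pd.DataFrame(rows).set_index("taxon")

    cat_rows = []
    for h in HABITATS:
        sub = taxon_rows[taxon_rows["habitat"] == h]
        if sub.empty:
            continue
        contrib = sub["contribution_percent"].dropna()
        row = {
            "habitat": h,
            "NI_total": int(sub["NI_total"].sum()),
            "contribution_percent": float(contrib.sum()) if len(contrib) else float("nan"),
        }
        if scats is not None:
            fo = frequency_of_occurrence(scats, tmap, h, cats)
            for g, v in fo.items():
                row[f"FO_{g}"] = v
        cat_rows.append(row)
    category_rows = pd.DataFrame(cat_rows).set_index("habitat")

    return ContributionTable(
        taxon_rows=taxon_rows,
        category_rows=category_rows,
        n_scats=int(n_scats),
        mean_dcb=float(mean_dcb),
        max_dcb=float(max_dcb),
    )


def select_sources(table: ContributionTable, threshold: float = 3.0) -> pd.DataFrame:
    """Taxa whose contribution strictly exceeds ``threshold`` percent.

    These become the candidate end-members for the isotope mixing model;
    the default 3% mirrors the smallest credible-interval width a pilot
    mixing run could resolve.
    """
    rows = table.taxon_rows
    keep = rows["contribution_percent"] > threshold
    return rows.loc[keep.fillna(False), ["habitat", "contribution_percent"]]


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def fisher_group_test(
    scats_by_group: dict[str, Sequence[ScatRecord]],
    taxa: Sequence[PreyTaxon] | dict[str, PreyTaxon],
    selector: str,
) -> dict:
    """Two-sided Fisher's exact test of selector occurrence between two groups.

    The 2x2 table is (contains at least one matching item) x (group); the
    two-sided p sums hypergeometric probabilities no larger than that of the
    observed table.
    """
    if len(scats_by_group) != 2:
        raise InvalidInputError("exactly two groups required")
    taxa = taxa if isinstance(taxa, dict) else {t.name: t for t in taxa}
    match = _resolve(selector, taxa)
    counts = []
    for g, scats in scats_by_group.items():
        n = len(scats)
        if n == 0:
            raise InvalidInputError(f"group {g!r} has no scats")
        k = sum(1 for s in scats if any(nm in match and c >= 1 for nm, c in s.items))
        counts.append((g, k, n - k))
    table = [[counts[0][1], counts[0][2]], [counts[1][1], counts[1][2]]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "groups": (counts[0][0], counts[1][0]),
        "odds_ratio": float(odds),
        "p_value": float(p),
    }
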