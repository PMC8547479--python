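"""Five-way assembly-process classification and fraction summaries.

Every pairwise comparison is assigned exactly one process from the
two-stage decision rule (thresholds strict, boundary values fall to the
less-significant category):

====================== ==========================================
variable_selection      betaNTI > 2
homogeneous_selection   betaNTI < -2
dispersal_limitation    |betaNTI| < 2 and RCbray > 0.95
homogenizing_dispersal  |betaNTI| < 2 and RCbray < -0.95
undominated             |betaNTI| < 2 and |RCbray| < 0.95
====================== ==========================================

Fractions are reported over sample groupings: all pairs, within-well
pairs, between-well pairs, or all pairs among wells of one pH category
(neutral 7.5-9, moderate 9-10.5, extreme 10.5-12 by default, assigned on
mean well pH or an explicit well-to-category map). Pairs with a
degenerate (NaN) betaNTI are tallied as excluded, never silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from assemblage.io import PairwiseMatrix, SampleMetadata, ValidationError

__all__ = [
    "PROCESSES",
    "BNTI_THRESHOLD",
    "RCBRAY_THRESHOLD",
    "AssemblyCall",
    "SampleGrouping",
    "ProcessFractions",
    "classify_pair",
    "classify_matrix",
    "build_groupings",
    "assign_ph_categories",
    "process_fractions",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RCBRAY_THRESHOLD = 0.95

PH_CATEGORIES = ("neutral", "moderate", "extreme")


@dataclass(frozen=True)
class AssemblyCall:
    """Per-pair process label with the scores that produced it."""

    pair: tuple[str, str]
    process: str
    bnti: float
    rcbray: float


@dataclass(frozen=True)
class SampleGrouping:
    """A named set of unordered sample pairs."""

    name: str
    pairs: frozenset[tuple[str, str]]
    definition: str

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)


@dataclass
class ProcessFractions:
    """Counts and percentages of each process within a grouping."""

    grouping: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n_pairs: int
    n_excluded: int
    calls: list[AssemblyCall] = field(default_factory=list, repr=False)


def classify_pair(bnti: float, rcbray: float = math.nan) -> str:
    """Assign one assembly process to a (betaNTI, RCbray) pair.

    RCbray is only consulted when |betaNTI| <= 2; it may be NaN otherwise.
    """
    if bnti is None or math.isnan(bnti):
        raise ValidationError("betaNTI must be finite to classify a pair")
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rcbray is None or math.isnan(rcbray):
        raise ValidationError(
            f"RCbray value required for non-significant betaNTI ({bnti:.3g})"
        )
    if rcbray > RCBRAY_THRESHOLD:
        return "dispersal_limitation"
    if rcbray < -RCBRAY_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def classify_matrix(
    bnti: PairwiseMatrix, rcbray: PairwiseMatrix, pairs=None
) -> tuple[list[AssemblyCall], list[tuple[str, str]]]:
    """Classify pairs from a betaNTI and an RCbray matrix.

    Returns (calls, excluded) where excluded lists pairs whose betaNTI is
    NaN (degenerate null).
    """
    if bnti.kind != "bnti" or rcbray.kind != "rcbray":
        raise ValidationError("matrices must have kinds 'bnti' and 'rcbray'")
    ids = bnti.ids
    if pairs is None:
        pairs = [
            SampleGrouping.canonical(a, b) for a, b in itertools.combinations(ids, 2)
        ]
    calls: list[AssemblyCall] = []
    excluded: list[tuple[str, str]] = []
    id_set = set(ids)
    rc_set = set(rcbray.ids)
    for a, b in pairs:
        if a not in id_set or b not in id_set:
            raise ValidationError(f"pair ({a}, {b}) absent from betaNTI matrix")
        if a not in rc_set or b not in rc_set:
            raise ValidationError(f"pair ({a}, {b}) absent from RCbray matrix")
        z = bnti.loc(a, b)
        if math.isnan(z):
            excluded.append((a, b))
            continue
        rc = rcbray.loc(a, b)
        calls.append(AssemblyCall((a, b), classify_pair(z, rc), z, rc))
    return calls, excluded


def assign_ph_categories(
    metadata: SampleMetadata,
    ph_breaks: tuple[float, float] = (9.0, 10.5),
    ph_bounds: tuple[float, float] = (7.5, 12.0),
    ph_map: dict[str, str] | None = None,
) -> dict[str, str]:
    """Well -> pH-category map, from an explicit map or mean well pH.

    Categories: neutral [lower bound, break1], moderate (break1, break2],
    extreme (break2, upper bound]. Wells with mean pH outside the bounds
    are omitted (and reported by their absence).
    """
    wells = sorted(set(str(w) for w in metadata.data["well_id"]))
    if ph_map is not None:
        unknown = [w for w in ph_map if w not in wells]
        if unknown:
            raise ValidationError(f"pH map names unknown wells: {unknown}")
        bad = [c for c in ph_map.values() if c not in PH_CATEGORIES]
        if bad:
            raise ValidationError(f"unknown pH categories: {sorted(set(bad))}")
        return dict(ph_map)
    if "pH" not in metadata.data.columns:
        raise ValidationError("metadata has no pH column and no explicit map was given")
    lo, hi = ph_bounds
    b1, b2 = ph_breaks
    out: dict[str, str] = {}
    ph = metadata.variable("pH")
    for well in wells:
        mean_ph = ph[metadata.data["well_id"].astype(str) == well].mean()
        if math.isnan(mean_ph) or mean_ph < lo or mean_ph > hi:
            continue
        if mean_ph <= b1:
            out[well] = "neutral"
        elif mean_ph <= b2:
            out[well] = "moderate"
        else:
            out[well] = "extreme"
    return out


def build_groupings(
    metadata: SampleMetadata,
    mode: str,
    ph_breaks: tuple[float, float] = (9.0, 10.5),
    ph_map: dict[str, str] | None = None,
) -> list[SampleGrouping]:
    """Sample-pair groupings for fraction summaries.

    Modes: ``all`` (every unordered pair), ``within_well`` (pairs sharing
    a well, i.e. time-series comparisons), ``between_well`` (pairs from
    different wells), ``ph_category`` (one grouping per category, pooling
    within- and between-well pairs among that category's wells).
    """
    samples = list(metadata.sample_ids)
    well_of = {s: str(w) for s, w in zip(samples, metadata.data["well_id"])}
    all_pairs = [SampleGrouping.canonical(a, b) for a, b in itertools.combinations(samples, 2)]
    if mode == "all":
        return [SampleGrouping("all", frozenset(all_pairs), "all")]
    if mode == "within_well":
        pairs = [p for p in all_pairs if well_of[p[0]] == well_of[p[1]]]
        return [SampleGrouping("within_well", frozenset(pairs), "within_well")]
    if mode == "between_well":
        pairs = [p for p in all_pairs if well_of[p[0]] != well_of[p[1]]]
        return [SampleGrouping("between_well", frozenset(pairs), "between_well")]
    if mode == "ph_category":
        categories = assign_ph_categories(metadata, ph_breaks=ph_breaks, ph_map=ph_map)
        groupings = []
        for cat in PH_CATEGORIES:
            wells = {w for w, c in categories.items() if c == cat}
            pairs = [
                p for p in all_pairs if well_of[p[0]] in wells and well_of[p[1]] in wells
            ]
            groupings.append(
                SampleGrouping(f"ph_{cat}", frozenset(pairs), f"ph_category({cat})")
            )
        return groupings
    raise ValueError(f"unknown grouping mode {mode!r}")


def process_fractions(
    bnti: PairwiseMatrix, rcbray: PairwiseMatrix, grouping: SampleGrouping
) -> ProcessFractions:
    """Per-process counts and percentages over a grouping's pairs."""
    pairs = sorted(grouping.pairs)
    if not pairs:
        raise ValidationError(f"grouping {grouping.name!r} contains no pairs")
    calls, excluded = classify_matrix(bnti, rcbray, pairs=pairs)
    n_pairs = len(pairs)
    n_excluded = len(excluded)
    if not calls:
        raise ValidationError(
            f"all {n_pairs} pairs in grouping {grouping.name!r} were excluded"
        )
    counts = {p: 0 for p in PROCESSES}
    for call in calls:
        counts[call.process] += 1
    denom = n_pairs - n_excluded
    percentages = {p: 100.0 * c / denom for p, c in counts.items()}
    return ProcessFractions(
        grouping=grouping.name,
        counts=counts,
        percentages=percentages,
        n_pairs=n_pairs,
        n_excluded=n_excluded,
        calls=calls,
    )
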