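"""Pedigree anticipation analysis on age-corrected telomere lengths.

Telomeres shorten with age, so comparing raw measured lengths across
generations conflates inheritance with aging.  The analysis projects each
individual's measured telomere length back to birth — the *initial
telomere length* — with a linear age correction:

    initial_kb = measured_kb + age_years * rate_bp_per_year / 1000

and then summarizes per-generation means and consecutive-generation
differences.  A positive difference (earlier generation minus later, in
bp) indicates genetic anticipation: successive generations inherit
shorter telomeres.

The shortening rate is a **required** input with no default: published
longitudinal adult rates vary (tens of bp/year) and childhood shortening
is considerably faster, so a silent default would bake in an assumption
the data may not support.  The linear correction matches standard
practice; an age-dependent (child/adult piecewise) rate is deliberately
not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import defaultdict

from .errors import PedigreeError
from .gelio import PedigreeRecord


def initial_tl(measured_tl_kb: float, age_years: float,
               rate_bp_per_year: float) -> float:
    """Initial (birth) telomere length in kb under a linear shortening rate.

    ``initial = measured + age * rate / 1000``; the rate is in bp/year and
    must be >= 0.
    """
    if rate_bp_per_year < 0:
        raise PedigreeError(
            f"shortening rate must be >= 0 bp/year, got {rate_bp_per_year}"
        )
    return measured_tl_kb + age_years * rate_bp_per_year / 1000.0


@dataclass(frozen=True)
class AnticipationSummary:
    """Per-individual and per-generation initial-TL summary.

    ``deltas`` maps consecutive generation pairs ``(g, g_next)`` to the
    mean initial-TL difference in bp, earlier minus later (positive =
    anticipation).  ``per_year_delta_bp`` divides the mean delta by the
    mean parent-child age gap and is only set when parental links were
    provided.
    """

    rate_bp_per_year: float
    per_individual: tuple[tuple[str, float], ...]
    per_generation: tuple[tuple[int, int, float], ...]  # (gen, n, mean kb)
    deltas: dict[tuple[int, int], float]
    monotone_anticipation: bool
    per_year_delta_bp: float | None = None

    def delta(self, g_from: int, g_to: int) -> float:
        """Mean initial-TL difference (bp) between two generations,
        antisymmetric: delta(a, b) = -delta(b, a)."""
        means = {g: m for g, _, m in self.per_generation}
        if g_from not in means or g_to not in means:
            raise PedigreeError(f"generation pair ({g_from}, {g_to}) not present")
        return (means[g_from] - means[g_to]) * 1000.0


def summarize_anticipation(records: list[PedigreeRecord],
                           rate_bp_per_year: float,
                           links: list[tuple[str, str]] | None = None
                           ) -> AnticipationSummary:
    """Age-correct a pedigree and summarize inter-generational differences.

    Requires at least two generations.  Consecutive-generation deltas are
    earlier-minus-later in bp; the summary *flags* monotone anticipation
    (every consecutive delta positive) but never asserts it.
    """
    if not records:
        raise PedigreeError("empty pedigree")
    generations = sorted({r.generation for r in records})
    if len(generations) < 2:
        raise PedigreeError(
            f"anticipation analysis needs >= 2 generations, got {generations}"
        )
    per_individual = tuple(
        (r.individual_id,
         initial_tl(r.measured_tl_kb, r.age_years, rate_bp_per_year))
        for r in records
    )
    by_gen: dict[int, list[float]] = defaultdict(list)
    for r, (_, init) in zip(records, per_individual):
        by_gen[r.generation].append(init)
    per_generation = tuple(
        (g, len(by_gen[g]), math.fsum(by_gen[g]) / len(by_gen[g]))
        for g in generations
    )
    means = {g: m for g, _, m in per_generation}
    deltas = {
        (g1, g2): (means[g1] - means[g2]) * 1000.0
        for g1, g2 in zip(generations[:-1], generations[1:])
    }
    monotone = all(d > 0 for d in deltas.values())

    per_year = None
    if links:
        by_id = {r.individual_id: r for r in records}
        gaps = []
        for parent_id, child_id in links:
            if parent_id not in by_id or child_id not in by_id:
                raise PedigreeError(
                    f"link ({parent_id}, {child_id}) names unknown individuals"
                )
            gaps.append(by_id[parent_id].age_years - by_id[child_id].age_years)
        mean_gap = math.fsum(gaps) / len(gaps)
        if mean_gap <= 0:
            raise PedigreeError(
                "mean parent-child age gap must be positive to express a "
                "per-year delta"
            )
        mean_delta = math.fsum(deltas.values()) / len(deltas)
        per_year = mean_delta / mean_gap

    return AnticipationSummary(
        rate_bp_per_year=rate_bp_per_year,
        per_individual=per_individual,
        per_generation=per_generation,
        deltas=deltas,
        monotone_anticipation=monotone,
        per_year_delta_bp=per_year,
    )


def summary_to_dict(summary: AnticipationSummary) -> dict:
    """JSON-serializable view of an AnticipationSummary."""
    return {
        "rate_bp_per_year": summary.rate_bp_per_year,
        "per_individual": [
            {"individual_id": i, "initial_tl_kb": v}
            for i, v in summary.per_individual
        ],
        "per_generation": [
            {"generation": g, "n": n, "mean_initial_tl_kb": m}
            for g, n, m in summary.per_generation
        ],
        "deltas_bp": [
            {"from_generation": g1, "to_generation": g2, "delta_bp": d}
            for (g1, g2), d in sorted(summary.deltas.items())
        ],
        "monotone_anticipation": summary.monotone_anticipation,
        "per_year_delta_bp": summary.per_year_delta_bp,
    }
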