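"""One-shot comparison of every recomputed quantity of the BAT analysis
against the published figures.

Each :class:`ComparisonRow` pairs a value recomputed through the public
module operations with the corresponding printed figure.  A row agrees when
the recomputed value rounds to the printed one at its printed precision, or
falls within the row's declared tolerance — propensity means carry ±0.05
(minor revisions of the Chou–Fasman table circulate), geometry rows carry
tolerances matching the "~" precision of the printed figures (the published
chain rounds intermediate lengths before differencing), and counts and the
feasibility flag are exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from . import geometry, kinetics
from .propensity import (
    FormerClassThresholds,
    PropensityTable,
    classify_residue_preferences,
    load_propensity_table,
)
from .sequences import syb2_cterminal_segment, syx1a_cterminal_segment

__all__ = ["ComparisonRow", "reference_comparison", "rows_to_tsv", "rows_to_json"]


@dataclass(frozen=True)
class ComparisonRow:
    quantity: str
    recomputed: float
    printed: float
    printed_precision: int
    tolerance: float
    agrees: bool
    location: str


def _row(
    quantity: str,
    recomputed: float,
    printed: float,
    precision: int,
    tolerance: float,
    location: str,
) -> ComparisonRow:
    agrees = (
        round(recomputed, precision) == printed
        or abs(recomputed - printed) <= tolerance
    )
    return ComparisonRow(quantity, recomputed, printed, precision, tolerance, agrees, location)


def reference_comparison(
    params: geometry.GeometryParams = geometry.GeometryParams(),
    kin: kinetics.KineticsParams = kinetics.KineticsParams(),
    table: PropensityTable | None = None,
    thresholds: FormerClassThresholds = FormerClassThresholds(),
) -> list[ComparisonRow]:
    """Recompute all published quantities of the BAT analysis as comparison rows.

    Every recomputed value is obtained through public module operations; no
    arithmetic is duplicated here.  The pore row feeds the published chained
    retraction (strand and helix lengths each rounded to one decimal before
    differencing) into ``pore_diameter``, mirroring how the published value
    was derived.
    """
    table = table or load_propensity_table()
    syb2 = classify_residue_preferences(syb2_cterminal_segment(), table, thresholds)
    syx1a = classify_residue_preferences(syx1a_cterminal_segment(), table, thresholds)
    n_syb, n_syx = len(syb2), len(syx1a)
    n_long = max(n_syb, n_syx)

    lb = geometry.length_beta(n_long, params)
    la = geometry.length_alpha(n_long, params)
    ret = geometry.retraction(n_long, params)
    chained_ret = round(lb, 1) - round(la, 1)
    span_bat = geometry.contact_span(n_syb, n_syx, geometry.BAT, params)
    span_short = geometry.contact_span(n_syb, n_syx, geometry.SHORT_BAT, params)
    gap = geometry.short_bat_central_gap(span_short, la)
    feasible = kinetics.feasibility(kin).feasible

    prop = "propensity discussion"
    geo = "transition geometry"
    contact = "contact-zone dimensions"
    rows = [
        _row("syb2 mean helix propensity", syb2.mean_alpha, 1.03, 2, 0.05, prop),
        _row("syb2 mean beta propensity", syb2.mean_beta, 1.36, 2, 0.05, prop),
        _row("syx1a mean helix propensity", syx1a.mean_alpha, 0.94, 2, 0.05, prop),
        _row("syx1a mean beta propensity", syx1a.mean_beta, 1.33, 2, 0.05, prop),
        _row("syb2 helix-preferring residues", syb2.n_helix_preferring, 4, 0, 0.0, prop),
        _row("syx1a helix-preferring residues", syx1a.n_helix_preferring, 3, 0, 0.0, prop),
        _row("beta-strand length, 23 residues (nm)", lb, 8.0, 1, 0.1, geo),
        _row("alpha-helix length, 23 residues (nm)", la, 3.5, 1, 0.1, geo),
        _row("retraction per strand (nm)", ret, 4.5, 1, 0.15, geo),
        _row(
            "initial fusion-pore diameter (nm)",
            geometry.pore_diameter(chained_ret, params),
            3.0,
            0,
            0.1,
            geo,
        ),
        _row("contact span, end-to-end pairs (nm)", span_bat, 16.0, 0, 0.5, contact),
        _row("contact span, side-by-side pairs (nm)", span_short, 8.0, 0, 0.5, contact),
        _row(
            "circular contact area, end-to-end (nm^2)",
            geometry.contact_area_circular(span_bat),
            200.0,
            0,
            10.0,
            contact,
        ),
        _row(
            "circular contact area, side-by-side (nm^2)",
            geometry.contact_area_circular(span_short),
            50.0,
            0,
            10.0,
            contact,
        ),
        _row("central hemi-fusion gap (nm)", gap, 1.0, 0, 0.2, contact),
        _row(
            "transition feasible within exocytosis latency",
            float(feasible),
            1.0,
            0,
            0.0,
            "kinetic feasibility",
        ),
    ]
    return rows


def rows_to_tsv(rows: list[ComparisonRow]) -> str:
    """Deterministic tab-delimited rendering ('.' decimals, LF endings)."""
    header = "quantity\trecomputed\tprinted\tprinted_precision\ttolerance\tagrees\tlocation"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.quantity}\t{r.recomputed:.6g}\t{r.printed:g}\t{r.printed_precision}"
            f"\t{r.tolerance:g}\t{str(r.agrees).lower()}\t{r.location}"
        )
    return "\n".join(lines) + "\n"


def rows_to_json(rows: list[ComparisonRow]) -> str:
    return json.dumps([asdict(r) for r in rows], indent=2) + "\n"
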