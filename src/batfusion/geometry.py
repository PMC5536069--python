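"""Geometric predictions of the β-to-α transition (BAT) fusion models.

An extended β-strand advances ~0.35 nm per residue, while an α-helix
advances 0.54 nm per 3.6-residue turn (0.15 nm per residue).  Converting a
membrane-embedded strand to helix therefore shortens it by ~0.20 nm per
residue; the BAT models turn that retraction into a fusion pore (each
retracting terminus picks up a lipid "coat" up to 3 nm wide) or, in the
side-by-side short-BAT variant, into parallel hemi-fused strips flanking a
narrow central gap.

All lengths are in nanometres, areas in nm².  Operations use unrounded
arithmetic; rounding to printed precision is left to reporting layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BAT",
    "SHORT_BAT",
    "GeometryParams",
    "BatGeometryResult",
    "GeometryError",
    "DYAD_CONTACT_AREA_NM2",
    "EM_CONTACT_AREA_NM2",
    "length_beta",
    "length_alpha",
    "retraction",
    "pore_diameter",
    "contact_span",
    "contact_area_circular",
    "short_bat_central_gap",
    "full_report",
]

#: Model-variant identifiers: end-to-end strand pairs vs side-by-side pairs.
BAT = "bat"
SHORT_BAT = "short-bat"
_VARIANTS = (BAT, SHORT_BAT)

#: Literature comparison constants, for report annotation only (never computed):
#: the dyad-model contact-area estimate and the large EM-measured contacts.
DYAD_CONTACT_AREA_NM2 = (70.0, 80.0)
EM_CONTACT_AREA_NM2 = 600.0  # reported lower bound, nm²


class GeometryError(ValueError):
    """Raised for invalid geometric inputs (negative counts/lengths, unknown variant)."""


@dataclass(frozen=True)
class GeometryParams:
    """Structural constants of the strand/helix geometry.

    beta_rise_per_residue : nm advanced per residue of extended β-strand.
    helix_rise_per_turn   : nm advanced per α-helical turn.
    residues_per_turn     : residues per α-helical turn.
    coat_width            : width (nm) of the lipid coat acquired by each
                            retracting C-terminus; "up to 3 nm".
    """

    beta_rise_per_residue: float = 0.35
    helix_rise_per_turn: float = 0.54
    residues_per_turn: float = 3.6
    coat_width: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "beta_rise_per_residue",
            "helix_rise_per_turn",
            "residues_per_turn",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.coat_width < 0:
            raise GeometryError("coat_width must be non-negative")
        if self.beta_rise_per_residue <= self.helix_rise_per_turn / self.residues_per_turn:
            raise GeometryError(
                "beta_rise_per_residue must exceed the helical rise per residue "
                "(otherwise the β→α transition would not shorten the strand)"
            )

    @property
    def helix_rise_per_residue(self) -> float:
        return self.helix_rise_per_turn / self.residues_per_turn


_DEFAULTS = GeometryParams()


def _check_count(n: int) -> None:
    if n < 0:
        raise GeometryError(f"residue count must be non-negative, got {n}")


def length_beta(n: int, params: GeometryParams = _DEFAULTS) -> float:
    """End-to-end length (nm) of an ``n``-residue extended β-strand."""
    _check_count(n)
    return n * params.beta_rise_per_residue


def length_alpha(n: int, params: GeometryParams = _DEFAULTS) -> float:
    """End-to-end length (nm) of an ``n``-residue α-helix."""
    _check_count(n)
    return (n / params.residues_per_turn) * params.helix_rise_per_turn


def retraction(n: int, params: GeometryParams = _DEFAULTS) -> float:
    """Shortening (nm) of an ``n``-residue strand upon full β→α conversion.

    Linear in ``n``: 0.20 nm per residue at the default constants.
    """
    return length_beta(n, params) - length_alpha(n, params)


def pore_diameter(retraction_per_side: float, params: GeometryParams = _DEFAULTS) -> float:
    """Initial fusion-pore diameter (nm) opened by strand retraction.

    Opposed strand pairs retract from both sides of their end-to-end
    junction, and each exposed terminus is wrapped by a lipid coat of
    ``params.coat_width``, so the open diameter is
    ``max(0, 2·retraction − 2·coat_width)``.
    """
    if retraction_per_side < 0:
        raise GeometryError("retraction_per_side must be non-negative")
    return max(0.0, 2.0 * retraction_per_side - 2.0 * params.coat_width)


def contact_span(
    n_syb: int, n_syx: int, variant: str, params: GeometryParams = _DEFAULTS
) -> float:
    """Width (nm) of the vesicle–plasma-membrane contact zone traversed by
    the β-structured anchors.

    End-to-end (BAT) pairs span the sum of the two strand lengths; the
    side-by-side (short-BAT) arrangement must accommodate the longer strand.
    """
    if n_syb < 1 or n_syx < 1:
        raise GeometryError("both residue counts must be >= 1")
    v = variant.strip().lower()
    if v == BAT:
        return length_beta(n_syb, params) + length_beta(n_syx, params)
    if v == SHORT_BAT:
        return max(length_beta(n_syb, params), length_beta(n_syx, params))
    raise GeometryError(f"unknown model variant {variant!r}; expected {_VARIANTS}")


def contact_area_circular(span: float) -> float:
    """Area (nm²) of an idealised circular contact zone of diameter ``span``."""
    if span < 0:
        raise GeometryError("span must be non-negative")
    return math.pi * (span / 2.0) ** 2


def short_bat_central_gap(pair_span: float, retracted_length: float) -> float:
    """Width (nm) of the central hemi-fused strip left between the two
    fully retracted side-by-side SNARE pairs.

    The pairs retract toward opposite anchor points across a strip of width
    ``pair_span``, each ending at ``retracted_length``; the uncovered centre
    is ``max(0, pair_span − 2·retracted_length)``.
    """
    if pair_span < 0 or retracted_length < 0:
        raise GeometryError("pair_span and retracted_length must be non-negative")
    return max(0.0, pair_span - 2.0 * retracted_length)


@dataclass(frozen=True)
class BatGeometryResult:
    """All derived geometry for one model variant.

    Per-strand fields (``length_beta`` … ``pore_diameter``) refer to the
    longer of the two hydrophobic anchors, whose dimensions set the spans
    and the central gap.  ``central_gap`` is ``None`` for the end-to-end
    variant.  The circular contact area is an idealisation ("if the contact
    zone were circular").
    """

    variant: str
    n_residues: int
    length_beta: float
    length_alpha: float
    retraction: float
    pore_diameter: float
    contact_span: float
    contact_area_circular: float
    central_gap: float | None = None


def full_report(
    n_syb: int, n_syx: int, params: GeometryParams = _DEFAULTS
) -> dict[str, BatGeometryResult]:
    """Compute a :class:`BatGeometryResult` for both model variants.

    Every field equals the corresponding single-purpose operation applied to
    the same inputs.
    """
    if n_syb < 1 or n_syx < 1:
        raise GeometryError("both residue counts must be >= 1")
    n_long = max(n_syb, n_syx)
    lb = length_beta(n_long, params)
    la = length_alpha(n_long, params)
    ret = retraction(n_long, params)
    pore = pore_diameter(ret, params)
    out = {}
    for variant in _VARIANTS:
        span = contact_span(n_syb, n_syx, variant, params)
        out[variant] = BatGeometryResult(
            variant=variant,
            n_residues=n_long,
            length_beta=lb,
            length_alpha=la,
            retraction=ret,
            pore_diameter=pore,
            contact_span=span,
            contact_area_circular=contact_area_circular(span),
            central_gap=short_bat_central_gap(span, la) if variant == SHORT_BAT else None,
        )
    return out
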