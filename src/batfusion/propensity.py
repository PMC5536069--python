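"""Chou–Fasman secondary-structure propensity analysis for short peptide segments.

The central objects are :class:`PropensityTable` (a named per-residue Pα/Pβ
scale), :class:`PeptideSegment` (a validated amino-acid window such as the
C-terminal hydrophobic anchor of a SNARE protein) and
:class:`PropensityReport` (per-residue values, region means and helix-vs-β
preference counts).  A propensity value above 1 means the residue is
over-represented in that secondary structure in the reference protein set;
region means above ~1.1 mark strong formers.

The scale shipped as ``"chou-fasman"`` is the classic Chou & Fasman (1978)
conformational-parameter set, the table distributed by the Biological
Magnetic Resonance Data Bank.  Minor revisions of this table circulate, so
the scale is a named, swappable resource rather than a hard-coded constant
inside the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "PropensityTable",
    "PeptideSegment",
    "ResidueScore",
    "PropensityReport",
    "FormerClassThresholds",
    "ScaleNotFoundError",
    "PropensityLookupError",
    "SequenceError",
    "load_propensity_table",
    "extract_cterminal_segment",
    "region_mean_propensities",
    "classify_residue_preferences",
    "score_mutant",
    "chou_fasman_segment_prediction",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ScaleNotFoundError(KeyError):
    """Raised when an unknown propensity-scale identifier is requested."""


class PropensityLookupError(KeyError):
    """Raised when a residue code is missing from a propensity table."""


class SequenceError(ValueError):
    """Raised for malformed or non-standard peptide sequences."""


@dataclass(frozen=True)
class PropensityTable:
    """A named per-residue secondary-structure propensity scale.

    ``values`` maps each of the 20 standard one-letter codes to a
    ``(p_alpha, p_beta, p_turn)`` triple; ``p_turn`` may be ``None`` for
    scales that do not define turn propensities.
    """

    scale_name: str
    values: Mapping[str, tuple[float, float, float | None]]
    provenance: str

    def __post_init__(self) -> None:
        present = set(self.values)
        expected = set(STANDARD_AMINO_ACIDS)
        if present != expected:
            missing = sorted(expected - present)
            extra = sorted(present - expected)
            raise ValueError(
                f"propensity table {self.scale_name!r} must cover exactly the 20 "
                f"standard residues (missing {missing}, unexpected {extra})"
            )
        for res, triple in self.values.items():
            for val in triple[:2] + ((triple[2],) if triple[2] is not None else ()):
                if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                    raise ValueError(
                        f"propensity for {res!r} in {self.scale_name!r} must be "
                        f"strictly positive and finite, got {val!r}"
                    )

    def _lookup(self, residue: str) -> tuple[float, float, float | None]:
        try:
            return self.values[residue]
        except KeyError:
            raise PropensityLookupError(
                f"residue {residue!r} is not in the {self.scale_name!r} scale "
                "(only the 20 standard one-letter codes are defined)"
            ) from None

    def alpha(self, residue: str) -> float:
        """Helix propensity Pα for a one-letter residue code."""
        return self._lookup(residue)[0]

    def beta(self, residue: str) -> float:
        """Strand propensity Pβ for a one-letter residue code."""
        return self._lookup(residue)[1]

    def turn(self, residue: str) -> float | None:
        return self._lookup(residue)[2]


# Chou & Fasman (1978) conformational parameters (Pα, Pβ, Pturn), the scale
# tabulated by the Biological Magnetic Resonance Data Bank.
_CHOU_FASMAN_1978: dict[str, tuple[float, float, float | None]] = {
    "A": (1.42, 0.83, 0.66),
    "R": (0.98, 0.93, 0.95),
    "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46),
    "C": (0.70, 1.19, 1.19),
    "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74),
    "G": (0.57, 0.75, 1.56),
    "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47),
    "L": (1.21, 1.30, 0.59),
    "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60),
    "F": (1.13, 1.38, 0.60),
    "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43),
    "T": (0.83, 1.19, 0.96),
    "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14),
    "V": (1.06, 1.70, 0.50),
}

_BUNDLED_SCALES: dict[str, tuple[Mapping[str, tuple[float, float, float | None]], str]] = {
    "chou-fasman": (
        _CHOU_FASMAN_1978,
        "Chou & Fasman (1978) conformational parameters, as tabulated by the "
        "Biological Magnetic Resonance Data Bank "
        "(http://www.bmrb.wisc.edu/referenc/choufas.shtml)",
    ),
}


def load_propensity_table(scale_id: str = "chou-fasman") -> PropensityTable:
    """Return a bundled, validated propensity scale by identifier.

    Raises
    ------
    ScaleNotFoundError
        If ``scale_id`` does not name a bundled scale.
    """
    try:
        values, provenance = _BUNDLED_SCALES[scale_id]
    except KeyError:
        raise ScaleNotFoundError(
            f"unknown propensity scale {scale_id!r}; "
            f"bundled scales: {sorted(_BUNDLED_SCALES)}"
        ) from None
    return PropensityTable(scale_name=scale_id, values=values, provenance=provenance)


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("sequence must be non-empty")
    for pos, ch in enumerate(seq, start=1):
        if ch not in STANDARD_AMINO_ACIDS:
            raise SequenceError(
                f"non-standard residue {ch!r} at position {pos} "
                "(only the 20 standard one-letter codes are accepted)"
            )
    return seq


@dataclass(frozen=True)
class PeptideSegment:
    """A named amino-acid sequence window with light structural annotation.

    Sequences are upper-cased and stripped on construction; anything outside
    the 20-letter standard alphabet is a hard error.  ``cysteine_positions``
    (1-based) is derived from the sequence — palmitoylation of those
    cysteines is annotated, never modelled numerically.  The
    ``c_terminal_charge_neutralized`` flag records the assumption that the
    terminal carboxyl charge is eliminated so the segment can sit in the
    membrane interior; it is annotation only.
    """

    id: str
    sequence: str
    source_protein: str = ""
    region_label: str = ""
    c_terminal_charge_neutralized: bool = False
    cysteine_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = _normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self,
            "cysteine_positions",
            tuple(i for i, ch in enumerate(seq, start=1) if ch == "C"),
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def glycine_positions(self) -> tuple[int, ...]:
        return tuple(i for i, ch in enumerate(self.sequence, start=1) if ch == "G")


def extract_cterminal_segment(
    full_sequence: str,
    n: int,
    id: str,
    *,
    source_protein: str = "",
    c_terminal_charge_neutralized: bool = False,
) -> PeptideSegment:
    """Extract the last ``n`` residues of a protein as a :class:`PeptideSegment`.

    The region label is set to ``"C-terminal n"``.  ``n`` must satisfy
    ``1 <= n <= len(full_sequence)``.
    """
    seq = _normalize_sequence(full_sequence)
    if n < 1:
        raise SequenceError(f"n must be >= 1, got {n}")
    if n > len(seq):
        raise SequenceError(
            f"cannot take the C-terminal {n} residues of a {len(seq)}-residue sequence"
        )
    return PeptideSegment(
        id=id,
        sequence=seq[-n:],
        source_protein=source_protein,
        region_label=f"C-terminal {n}",
        c_terminal_charge_neutralized=c_terminal_charge_neutralized,
    )


def _per_residue(
    segment: PeptideSegment, table: PropensityTable
) -> list[tuple[int, str, float, float]]:
    out = []
    for i, res in enumerate(segment.sequence, start=1):
        try:
            pa, pb = table.alpha(res), table.beta(res)
        except PropensityLookupError as exc:
            raise PropensityLookupError(
                f"segment {segment.id!r}: {exc.args[0]} (position {i})"
            ) from None
        out.append((i, res, pa, pb))
    return out


def region_mean_propensities(
    segment: PeptideSegment, table: PropensityTable
) -> tuple[float, float]:
    """Unweighted arithmetic means ``(mean_alpha, mean_beta)`` over a segment.

    Order-invariant by construction: the mean depends only on residue
    composition.
    """
    rows = _per_residue(segment, table)
    n = len(rows)
    return (
        sum(pa for _, _, pa, _ in rows) / n,
        sum(pb for _, _, _, pb in rows) / n,
    )


@dataclass(frozen=True)
class FormerClassThresholds:
    """Cut-offs mapping a region-mean propensity onto a verbal former class.

    Defaults: mean ≥ 1.10 → "strong former"; [1.00, 1.10) → "weak former";
    [0.90, 1.00) → "indifferent"; < 0.90 → "breaker-leaning".
    """

    strong: float = 1.10
    weak: float = 1.00
    indifferent: float = 0.90

    def classify(self, mean: float) -> str:
        if mean >= self.strong:
            return "strong former"
        if mean >= self.weak:
            return "weak former"
        if mean >= self.indifferent:
            return "indifferent"
        return "breaker-leaning"


@dataclass(frozen=True)
class ResidueScore:
    index: int  # 1-based position within the segment
    residue: str
    p_alpha: float
    p_beta: float
    preference: str  # "helix" | "beta" | "tie"


@dataclass(frozen=True)
class PropensityReport:
    """Per-residue propensities and region-level summary for one segment.

    ``n_helix_preferring`` counts residues whose helix propensity strictly
    exceeds their strand propensity; ties are counted separately and never
    assigned to either side.  ``modifications_not_modeled`` records that
    cysteine palmitoylation is annotated but excluded from the numbers.
    """

    segment_id: str
    per_residue: tuple[ResidueScore, ...]
    mean_alpha: float
    mean_beta: float
    n_helix_preferring: int
    n_beta_preferring: int
    n_tie: int
    alpha_former_class: str
    beta_former_class: str
    glycine_positions: tuple[int, ...]
    cysteine_positions: tuple[int, ...]
    modifications_not_modeled: bool = True

    def __len__(self) -> int:
        return len(self.per_residue)


def classify_residue_preferences(
    segment: PeptideSegment,
    table: PropensityTable,
    thresholds: FormerClassThresholds = FormerClassThresholds(),
) -> PropensityReport:
    """Score each residue as helix- or β-preferring and summarise the region.

    A residue prefers helix iff Pα > Pβ (strict), β iff Pβ > Pα, and is a
    tie otherwise.  Region means are classified into verbal former classes
    via ``thresholds``.
    """
    rows = _per_residue(segment, table)
    scores = []
    n_helix = n_beta = n_tie = 0
    for i, res, pa, pb in rows:
        if pa > pb:
            pref = "helix"
            n_helix += 1
        elif pb > pa:
            pref = "beta"
            n_beta += 1
        else:
            pref = "tie"
            n_tie += 1
        scores.append(ResidueScore(i, res, pa, pb, pref))
    n = len(rows)
    mean_alpha = sum(pa for _, _, pa, _ in rows) / n
    mean_beta = sum(pb for _, _, _, pb in rows) / n
    return PropensityReport(
        segment_id=segment.id,
        per_residue=tuple(scores),
        mean_alpha=mean_alpha,
        mean_beta=mean_beta,
        n_helix_preferring=n_helix,
        n_beta_preferring=n_beta,
        n_tie=n_tie,
        alpha_former_class=thresholds.classify(mean_alpha),
        beta_former_class=thresholds.classify(mean_beta),
        glycine_positions=segment.glycine_positions,
        cysteine_positions=segment.cysteine_positions,
    )


def score_mutant(
    segment: PeptideSegment,
    substitutions: Sequence[tuple[int, str]],
    table: PropensityTable,
    thresholds: FormerClassThresholds = FormerClassThresholds(),
) -> tuple[PropensityReport, float, float]:
    """Apply point substitutions and report the change in region means.

    ``substitutions`` is a list of ``(position, new_residue)`` with 1-based
    positions.  Returns ``(mutant_report, delta_mean_alpha, delta_mean_beta)``
    where the deltas are mutant minus wild type.  Used for what-if scoring of
    helix- vs β-stabilising mutations of the hydrophobic anchors.
    """
    seq = list(segment.sequence)
    for pos, new in substitutions:
        if not (1 <= pos <= len(seq)):
            raise SequenceError(
                f"substitution position {pos} outside segment "
                f"{segment.id!r} (length {len(seq)})"
            )
        new = new.strip().upper()
        if len(new) != 1 or new not in STANDARD_AMINO_ACIDS:
            raise SequenceError(f"invalid replacement residue {new!r} at position {pos}")
        seq[pos - 1] = new
    mutant = PeptideSegment(
        id=f"{segment.id}|mut",
        sequence="".join(seq),
        source_protein=segment.source_protein,
        region_label=segment.region_label,
        c_terminal_charge_neutralized=segment.c_terminal_charge_neutralized,
    )
    wt_alpha, wt_beta = region_mean_propensities(segment, table)
    report = classify_residue_preferences(mutant, table, thresholds)
    return report, report.mean_alpha - wt_alpha, report.mean_beta - wt_beta


# --- windowed Chou–Fasman state prediction -----------------------------------
#
# Deterministic nucleation/extension rules, documented here because variants
# of the original algorithm abound:
#   * helix nucleates where any 6-residue window holds >= 4 residues with
#     Pα > 1.00; strand nucleates where any 5-residue window holds >= 3
#     residues with Pβ > 1.00;
#   * a nucleated run extends one residue at a time while the 4-residue
#     window entered at the new edge keeps a mean propensity >= 1.00;
#   * where helix and strand runs overlap, the whole overlapping stretch is
#     assigned to the structure with the larger regional mean.
# This is an extension convenience beyond the region-mean analysis, not a
# substitute for experimental structure determination.

_HELIX_WINDOW, _HELIX_MIN = 6, 4
_STRAND_WINDOW, _STRAND_MIN = 5, 3
_EXT_WINDOW = 4


def _nucleate_and_extend(p: Sequence[float], window: int, minimum: int) -> list[bool]:
    n = len(p)
    mask = [False] * n
    for start in range(n - window + 1):
        if sum(1 for v in p[start : start + window] if v > 1.00) >= minimum:
            for i in range(start, start + window):
                mask[i] = True
    # extend each maximal run while the entered 4-window mean stays >= 1.00
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if mask[i]:
                continue
            left_run = i + 1 < n and mask[i + 1]
            right_run = i - 1 >= 0 and mask[i - 1]
            if not (left_run or right_run):
                continue
            if right_run:
                win = p[max(0, i - _EXT_WINDOW + 1) : i + 1]
            else:
                win = p[i : i + _EXT_WINDOW]
            if sum(win) / len(win) >= 1.00:
                mask[i] = True
                changed = True
    return mask


def chou_fasman_segment_prediction(
    segment: PeptideSegment, table: PropensityTable
) -> str:
    """Predict a per-residue H/E/C state string for a segment.

    Requires at least 6 residues (the helix nucleation window).
    """
    n = len(segment)
    if n < _HELIX_WINDOW:
        raise SequenceError(
            f"segment {segment.id!r} has {n} residues; "
            f"prediction needs at least {_HELIX_WINDOW}"
        )
    pa = [table.alpha(r) for r in segment.sequence]
    pb = [table.beta(r) for r in segment.sequence]
    helix = _nucleate_and_extend(pa, _HELIX_WINDOW, _HELIX_MIN)
    strand = _nucleate_and_extend(pb, _STRAND_WINDOW, _STRAND_MIN)
    states = []
    i = 0
    while i < n:
        if helix[i] and strand[i]:
            j = i
            while j < n and helix[j] and strand[j]:
                j += 1
            mean_a = sum(pa[i:j]) / (j - i)
            mean_b = sum(pb[i:j]) / (j - i)
            states.extend(("H" if mean_a >= mean_b else "E") * (j - i))
            i = j
        else:
            states.append("H" if helix[i] else "E" if strand[i] else "C")
            i += 1
    return "".join(states)
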