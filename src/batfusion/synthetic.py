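"""Synthetic peptide segments with controlled propensity statistics.

Real membrane-anchor segments are short, hydrophobic and have region-mean
helix/strand propensities in a narrow band; the generator emulates exactly
that statistical structure (composition-driven region means over a chosen
alphabet) so every analysis stage can be exercised without external data.
It does not emulate residue ordering constraints, conservation, or any
membrane physics — region means are composition statistics, so that is the
only feature controlled.

Algorithm: random initialisation from the allowed alphabet followed by
greedy single-residue swaps that minimise the squared deviation of the
region means from the stated targets.  Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fastaio import FastaRecord, write_fasta
from .propensity import (
    STANDARD_AMINO_ACIDS,
    PeptideSegment,
    PropensityTable,
    load_propensity_table,
    region_mean_propensities,
    score_mutant,
)
from .sequences import syb2_cterminal_segment, syx1a_cterminal_segment

__all__ = [
    "HYDROPHOBIC_ALPHABET",
    "SequenceGenSpec",
    "GenerationError",
    "generate_segment",
    "make_fixture_set",
]

#: Residue classes seen in SNARE anchor domains (membrane-like segments).
HYDROPHOBIC_ALPHABET = "ACFGILMSTVWY"


class GenerationError(RuntimeError):
    """Raised when a target composition cannot be reached."""


@dataclass(frozen=True)
class SequenceGenSpec:
    """Specification for one synthetic segment.

    Targets are region-mean propensities; ``None`` leaves that mean free.
    ``tolerance`` is the maximum absolute deviation of each stated target.
    """

    length: int
    target_mean_alpha: float | None = None
    target_mean_beta: float | None = None
    hydrophobic_only: bool = False
    random_seed: int = 0
    tolerance: float = 0.02
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _alphabet(spec: SequenceGenSpec) -> str:
    return HYDROPHOBIC_ALPHABET if spec.hydrophobic_only else STANDARD_AMINO_ACIDS


def _check_target_achievable(
    name: str, target: float | None, values: dict[str, float]
) -> None:
    if target is None:
        return
    lo, hi = min(values.values()), max(values.values())
    if not (lo <= target <= hi):
        raise GenerationError(
            f"{name} target {target} outside the achievable range "
            f"[{lo}, {hi}] for the allowed alphabet"
        )


def _loss(
    seq: list[str],
    spec: SequenceGenSpec,
    pa: dict[str, float],
    pb: dict[str, float],
) -> float:
    n = len(seq)
    loss = 0.0
    if spec.target_mean_alpha is not None:
        loss += (sum(pa[r] for r in seq) / n - spec.target_mean_alpha) ** 2
    if spec.target_mean_beta is not None:
        loss += (sum(pb[r] for r in seq) / n - spec.target_mean_beta) ** 2
    return loss


def _within_tolerance(
    seq: list[str],
    spec: SequenceGenSpec,
    pa: dict[str, float],
    pb: dict[str, float],
) -> bool:
    n = len(seq)
    if spec.target_mean_alpha is not None:
        if abs(sum(pa[r] for r in seq) / n - spec.target_mean_alpha) > spec.tolerance:
            return False
    if spec.target_mean_beta is not None:
        if abs(sum(pb[r] for r in seq) / n - spec.target_mean_beta) > spec.tolerance:
            return False
    return True


def generate_segment(
    spec: SequenceGenSpec,
    table: PropensityTable | None = None,
    *,
    id: str | None = None,
) -> PeptideSegment:
    """Generate a segment whose region means meet the spec's targets.

    Raises :class:`GenerationError` if a target lies outside the achievable
    range of the alphabet or the greedy search stalls before reaching
    tolerance; the error message reports the best means achieved.
    """
    table = table or load_propensity_table()
    alphabet = _alphabet(spec)
    pa = {r: table.alpha(r) for r in alphabet}
    pb = {r: table.beta(r) for r in alphabet}
    _check_target_achievable("mean_alpha", spec.target_mean_alpha, pa)
    _check_target_achievable("mean_beta", spec.target_mean_beta, pb)

    rng = np.random.default_rng(spec.random_seed)
    seq = list(rng.choice(list(alphabet), size=spec.length))
    iters = 0
    while not _within_tolerance(seq, spec, pa, pb):
        best = (None, None, _loss(seq, spec, pa, pb))
        for pos in range(spec.length):
            current = seq[pos]
            for res in alphabet:
                if res == current:
                    continue
                seq[pos] = res
                loss = _loss(seq, spec, pa, pb)
                if loss < best[2]:
                    best = (pos, res, loss)
            seq[pos] = current
        iters += 1
        if best[0] is None or iters > spec.max_iterations:
            a, b = _means(seq, pa, pb)
            raise GenerationError(
                f"could not reach targets within tolerance {spec.tolerance} "
                f"(best achieved mean_alpha={a:.4f}, mean_beta={b:.4f})"
            )
        seq[best[0]] = best[1]
    return PeptideSegment(
        id=id or f"synthetic-L{spec.length}-s{spec.random_seed}",
        sequence="".join(seq),
        source_protein="synthetic",
        region_label=f"synthetic {spec.length}-mer",
    )


def _means(seq: list[str], pa: dict[str, float], pb: dict[str, float]) -> tuple[float, float]:
    n = len(seq)
    return sum(pa[r] for r in seq) / n, sum(pb[r] for r in seq) / n


def make_fixture_set(
    seed: int, out_path: str | Path | None = None
) -> list[FastaRecord]:
    """Build the standard fixture collection, optionally writing FASTA.

    Records: the two reference anchor segments, a β-matched hydrophobic
    control (same mean β propensity as the synaptobrevin anchor, within
    0.02), an α-shifted variant of the synaptobrevin anchor (every Ile→Leu,
    which raises mean Pα and lowers mean Pβ), and two unconstrained random
    controls.  Headers carry provenance notes.
    """
    table = load_propensity_table()
    syb2 = syb2_cterminal_segment()
    syx1a = syx1a_cterminal_segment()
    _, syb2_beta = region_mean_propensities(syb2, table)

    beta_matched = generate_segment(
        SequenceGenSpec(
            length=len(syb2),
            target_mean_beta=syb2_beta,
            hydrophobic_only=True,
            random_seed=seed,
        ),
        table,
        id="beta-matched-control",
    )
    ile_positions = [i for i, r in enumerate(syb2.sequence, start=1) if r == "I"]
    alpha_report, _, _ = score_mutant(syb2, [(i, "L") for i in ile_positions], table)
    randoms = [
        generate_segment(
            SequenceGenSpec(length=len(syb2), random_seed=seed + k),
            table,
            id=f"random-control-{k}",
        )
        for k in (1, 2)
    ]

    records = [
        FastaRecord(syb2.id, syb2.sequence, "C-terminal hydrophobic anchor, mouse synaptobrevin 2"),
        FastaRecord(syx1a.id, syx1a.sequence, "C-terminal hydrophobic anchor, mouse syntaxin 1A"),
        FastaRecord(
            beta_matched.id,
            beta_matched.sequence,
            f"synthetic hydrophobic control, mean beta matched to {syb2.id} (seed {seed})",
        ),
        FastaRecord(
            "alpha-shifted-syb2",
            "".join(s.residue for s in alpha_report.per_residue),
            "synthetic helix-favoring variant of the synaptobrevin anchor (all Ile->Leu)",
        ),
        *[
            FastaRecord(r.id, r.sequence, f"synthetic unconstrained control (seed {seed})")
            for r in randoms
        ],
    ]
    if out_path is not None:
        write_fasta(records, out_path)
    return records
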