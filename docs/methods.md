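# Methods

## The model in brief

The β-to-α transition (BAT) picture of SNARE-mediated exocytosis holds
that the C-terminal hydrophobic anchors of synaptobrevin 2 and syntaxin 1A
lie between the membrane leaflets as extended β-strands before fusion,
and that completion of SNARE zippering propagates an α-helical conversion
into them. Because a strand advances ~0.35 nm per residue and a helix only
~0.15 nm per residue, the conversion physically shortens the anchors; the
models turn that retraction into an initial fusion pore (end-to-end
arrangement) or parallel hemi-fused strips around a narrow central gap
(side-by-side, "short" arrangement). The package implements the three
quantitative legs of that argument — composition-based secondary-structure
propensity, retraction geometry, and a folding-timescale bound — as
independent, composable operations.

## Propensity analysis

The bundled `"chou-fasman"` scale is the classic Chou & Fasman (1978)
conformational-parameter set (Pα, Pβ, Pturn per residue), the table
distributed by the Biological Magnetic Resonance Data Bank. Minor
revisions of these constants circulate, so the scale is a named, swappable
resource carrying provenance text, and comparisons against published means
carry a ±0.05 tolerance. With this table the recomputed region means are
1.06/1.37 (synaptobrevin anchor, α/β) and 0.97/1.29 (syntaxin anchor)
against published values of 1.03/1.36 and 0.94/1.33 — consistent at that
tolerance, with the residual differences attributable to the table
revision used by the original analysis. The helix-preferring counts (4 and
3) and the strand-former classification reproduce exactly.

Conventions:

* Region means are unweighted arithmetic means over the segment; they are
  composition statistics, hence permutation-invariant and additive under
  concatenation (length-weighted).
* A residue prefers helix iff Pα > Pβ **strictly**; ties are tallied
  separately and never credited to either side, matching the strict
  "preference exceeds" counting of the published analysis.
* Verbal former classes from a region mean *m*: *m* ≥ 1.10 strong former;
  1.00 ≤ *m* < 1.10 weak former; 0.90 ≤ *m* < 1.00 indifferent; *m* < 0.90
  breaker-leaning. The thresholds are a config-exposed dataclass; the
  defaults were chosen so the published verbal labels ("weak" at ~1.03,
  "strong β former" at ~1.36, "cusp of weak-to-indifferent" at ~0.94)
  reproduce.
* Sequences are upper-cased and stripped on ingest; any character outside
  the 20-letter standard alphabet is a hard error, and a residue missing
  from a table raises an error naming the residue and position — there are
  no silent defaults.
* Cysteine palmitoylation and C-terminal charge neutralisation are carried
  as annotations only (`cysteine_positions`,
  `c_terminal_charge_neutralized`, `modifications_not_modeled`); no
  modification energetics are computed.

The windowed H/E/C state prediction (`chou_fasman_segment_prediction`) is
an extension convenience beyond the region-mean analysis: helix nucleates
where any 6-residue window has ≥ 4 residues with Pα > 1.00, strand where
any 5-residue window has ≥ 3 with Pβ > 1.00; runs extend while the
4-residue window entered at the edge keeps mean ≥ 1.00; helix/strand
overlaps go to the larger regional mean. It is deterministic and
documented here precisely because published variants of the original
algorithm differ in these details.

## Geometry

Structural constants (all config-exposed via `GeometryParams`, lengths in
nm): β rise 0.35 nm/residue; helix rise 0.54 nm per 3.6-residue turn;
lipid-coat width 3.0 nm (the published "up to 3 nm" is taken as the
default upper value; sweeps over [0, 3] are legitimate). Validation
rejects constants under which the β→α conversion would not shorten the
strand.

Derived quantities: strand length `n·0.35`; helix length `n/3.6·0.54`;
retraction is their difference (0.20 nm/residue at defaults); pore
diameter `max(0, 2·retraction − 2·coat)` — the published account states
the retraction, the coat and the ~3 nm result without the formula, and
this reconstruction reproduces the printed number exactly. The end-to-end
contact span is the sum of the two strand lengths; the side-by-side span
is the **max** of the two (the zone must accommodate the longer strand;
an explicit span can be supplied instead). Circular contact areas
π(span/2)² are flagged as idealisations. The short-variant central gap is
`max(0, pair_span − 2·retracted_length)`, a reconstruction that reproduces
the published ~1 nm but is not written out in the source account. The
dyad-model 70–80 nm² and the > 600 nm² electron-microscopy contact areas
are stored as literature constants for annotation only, never computed.

All operations use unrounded arithmetic. The published chain rounds
intermediate values (8.0 − 3.5 = 4.5 nm, area from a rounded 16 nm span),
so the comparison report carries per-row tolerances matching the "~"
precision of each printed figure, and the pore row feeds the
rounded-chain retraction into the pore formula as the published derivation
does. `full_report` fields are definitionally equal to the single-purpose
operations; its per-strand values refer to the longer anchor (23
residues), whose dimensions set the spans and the gap.

## Kinetics

`KineticsParams` encodes the timescale bound: base fold time 1.0 µs (a
conservative upper encoding of "sub-microsecond" helix folding for a
~20-residue motif), slowdown factor 20 (membrane milieu penalty), and
exocytosis latency 50 µs. Feasible iff base × slowdown ≤ latency, boundary
inclusive; the margin is latency divided by the effective time. No
helix–coil statistical mechanics, temperature dependence or zippering rate
model is attempted — the published argument is a bound, and simulating
rates would be invention beyond it. Whether the four strands convert
sequentially or concurrently is not specified anywhere; the quoted
motif-folding time is treated as the timescale of the whole event.

## Synthetic sequences

`generate_segment` emulates the statistical structure the propensity
analysis actually consumes: short segments with controllable region-mean
Pα/Pβ over a chosen alphabet (optionally the membrane-like hydrophobic set
A C F G I L M S T V W Y, matching the residue classes of SNARE anchors).
Algorithm: seeded random initialisation, then greedy best single-residue
substitution minimising the squared deviation of the means from the
targets, until every stated target is within tolerance (default 0.02).
Greedy swapping was chosen over rejection sampling for reliability at
tight tolerances; runs are deterministic for a fixed seed, unachievable
targets (outside the alphabet's propensity range) fail fast, and a stalled
search raises with the best means achieved. `make_fixture_set` bundles the
two real anchors, a β-matched hydrophobic control, a helix-shifted variant
(every Ile→Leu, which provably raises mean Pα and lowers mean Pβ on this
scale) and two unconstrained random controls, with provenance in the FASTA
headers.

What the generator does **not** emulate: residue ordering, evolutionary
conservation, hydrophobic-moment periodicity or any membrane physics.
Passing tests therefore demonstrate correctness of the composition
statistics and the pipeline around them, not biological realism of the
synthetic sequences.

## Reference sequences

The bundled full-length mouse synaptobrevin 2 and syntaxin 1A sequences
follow the canonical UniProt entries (P63044, O35526). The analysis rests
only on their C-terminal anchors (last 22 and 23 residues), which satisfy
every independent check available: one cysteine and one glycine in the
synaptobrevin anchor, tandem cysteines and multiple glycines in the
syntaxin anchor, and the 4/3 helix-preferring counts.

## Numerical and testing conventions

* Floating comparisons in tests use absolute tolerances ≤ 1e-12 for exact
  identities (means vs naive-loop oracle, concatenation additivity) and
  the published precision for paper-derived values.
* Property tests (hypothesis, derandomised) cover permutation invariance,
  concatenation, count conservation, mutation-delta consistency, geometry
  linearity/monotonicity and the kinetics margin identity; a 1,000-segment
  seeded sweep checks oracle equivalence at scale and a 100-seed sweep
  checks generator target recovery (≥ 95% within 0.02). The whole suite
  runs in a few seconds on one CPU.
* Degenerate inputs: zero-length geometry is allowed (0 nm) but zero
  residue counts are rejected where a physical strand is implied
  (`contact_span`, `full_report`); empty FASTA files parse to an empty
  list; empty substitution lists are exact identities.

## Known limitations

Composition-mean propensity is a coarse instrument — it ignores context,
pairing and the membrane environment, and the underlying statistics come
from soluble proteins. The geometry is rigid-rod arithmetic with no
continuum mechanics, lipid physics, membrane tension or helix splaying,
and the circular contact zone is an idealisation. The kinetics check is a
single multiplicative bound, not a rate model. These are faithful limits
of the modelling framework itself, which argues from exactly these
desk-scale quantities.
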