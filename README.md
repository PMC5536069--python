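# batfusion

Quantitative analysis for the **β-to-α transition (BAT) models** of
SNARE-mediated membrane fusion: the hypothesis that the C-terminal
hydrophobic anchors of synaptobrevin 2 (VAMP2) and syntaxin 1A sit in the
membrane as extended β-strands before fusion and convert to α-helix upon
full SNARE zippering, and that the resulting physical shortening of the
anchors is what opens the fusion pore.

The package is for structural/synaptic biologists who want the three
strands of that argument as reusable, tested calculations:

1. **Propensity analysis** (`batfusion.propensity`). Chou–Fasman
   conformational parameters Pα/Pβ assign each residue a statistical
   preference for helix or strand (P > 1 ⇒ over-represented in that
   structure). For a segment of *n* residues the region means are

   &nbsp;&nbsp; P̄ₓ = (1/n) Σᵢ Pₓ(residueᵢ),  x ∈ {α, β},

   and a residue "prefers" helix only if Pα > Pβ strictly. Applied to the
   last 22 residues of mouse synaptobrevin 2 and the last 23 of mouse
   syntaxin 1A, composition favours β-structure: strand means near 1.3–1.4
   (strong formers) against weak-to-indifferent helix means, with only 4
   and 3 helix-preferring residues respectively and helix-breaking
   glycines in both anchors.

2. **Geometry** (`batfusion.geometry`). A β-strand advances 0.35 nm per
   residue; an α-helix 0.54 nm per 3.6-residue turn (0.15 nm/residue).
   Conversion of an *n*-residue strand therefore retracts it by
   ≈ 0.20·*n* nm. With each retracting terminus coated by up to 3 nm of
   lipid, the initial pore diameter is max(0, 2·retraction − 2·coat).
   Contact-zone spans and idealised circular areas follow for the
   end-to-end ("bat") and side-by-side ("short-bat") arrangements, as does
   the ~1 nm central hemi-fused strip of the short variant.

3. **Kinetics** (`batfusion.kinetics`). A ~20-residue helix folds in under
   a microsecond; even 20-fold slower in the membrane the transition
   (~20 µs) fits inside the ~50 µs latency of synchronous exocytosis.

A composition-controlled sequence generator (`batfusion.synthetic`)
produces peptide fixtures with prescribed mean propensities so every stage
is testable without external data, and `batfusion.report` recomputes every
published figure of the analysis side by side with the package's numbers.

## Worked example

```python
>>> from batfusion import (classify_residue_preferences,
...     load_propensity_table, syb2_cterminal_segment, full_report)
>>> table = load_propensity_table("chou-fasman")
>>> rep = classify_residue_preferences(syb2_cterminal_segment(), table)
>>> round(rep.mean_alpha, 2), round(rep.mean_beta, 2), rep.n_helix_preferring
(1.06, 1.37, 4)
```

The synaptobrevin anchor averages a strand propensity of 1.37 (strong β
former) against a helix mean of 1.06 (weak former), and only 4 of its 22
residues individually prefer helix — the composition argument for a
pre-fusion β-state. On the geometry side:

```python
>>> r = full_report(n_syb=22, n_syx=23)["short-bat"]
>>> round(r.retraction, 2), round(r.contact_span, 2), round(r.central_gap, 2)
(4.6, 8.05, 1.15)
```

Full conversion retracts the 23-residue strand by 4.6 nm across an
~8 nm side-by-side contact zone, leaving a ~1 nm central hemi-fused strip.
The same numbers are available from the shell:

```sh
batfusion report          # all published quantities vs recomputed, TSV
batfusion geometry --n-syb 22 --n-syx 23 --variant bat
batfusion kinetics --slowdown 20
batfusion simulate --length 22 --target-beta 1.36 --seed 7 --out fixtures.fa
```

`batfusion report` exits non-zero if any recomputed value disagrees with
its published counterpart beyond the row's declared tolerance. Short
narrative scripts covering each capability live in `examples/`.

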