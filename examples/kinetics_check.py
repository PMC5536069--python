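"""Is a propagated β→α transition fast enough for synchronous exocytosis?

Helical folding of a ~20-residue motif takes under a microsecond in
solution; even slowed 20-fold in the membrane milieu the transition takes
~20 µs, comfortably inside the ~50 µs latency between the Ca²⁺ rise and
exocytosis.  The margin is latency / effective transition time.
"""

from batfusion import KineticsParams, effective_transition_time, feasibility

for slowdown in (1.0, 20.0, 100.0):
    params = KineticsParams(base_fold_time=1.0, slowdown_factor=slowdown,
                            exocytosis_latency=50.0)
    res = feasibility(params)
    print(
        f"slowdown x{slowdown:>5.0f}: transition {effective_transition_time(params):6.1f} us"
        f"  -> feasible={res.feasible}  margin={res.margin:.2f}"
    )
# Only an implausibly large (100-fold) slowdown pushes the transition past
# the exocytosis latency.
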