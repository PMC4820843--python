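"""Single-cell qPCR analysis: ΔCt to Kit, frequency and level comparisons.

Simulates a Biomark-style Ct matrix, drops Kit-negative cells, normalizes
each cell to its Kit Ct (ΔCt = Ct_Kit - Ct_assay, larger = higher
expression), then compares detection frequencies (chi-square), expression
levels among positive cells (t-test) and panel co-expression breadth (KS).
"""

import hscbias as hb

ct, truth, groups = hb.simulate_ct(hb.CtSimulationConfig(seed=2))
delta = hb.delta_ct(ct, cell_groups=groups)
print(f"cells retained: {len(delta.cell_ids)}, "
      f"excluded (Kit-negative): {len(delta.excluded_cells)}")

freq = hb.expression_frequency(delta, group_a="old", group_b="young")
level = hb.expression_level_test(delta, group_a="old", group_b="young")
print(f"{'assay':8} {'freq old':>9} {'freq young':>11} {'p(chi2)':>10} "
      f"{'dCt old':>8} {'dCt young':>10} {'p(t)':>10}")
for f, l in zip(freq, level):
    if f.assay_id == delta.reference_assay:
        continue
    print(f"{f.assay_id:8} {f.freq_a:9.3f} {f.freq_b:11.3f} {f.p_freq:10.2e} "
          f"{l.mean_delta_a:8.2f} {l.mean_delta_b:10.2f} "
          f"{l.p_level:10.2e}" if not l.untestable else f"{f.assay_id}: untestable")

panel = hb.GeneSet("platelet_panel", {"Vwf", "Itgb3", "Gata1"})
D, p = hb.coexpression_ks(delta, panel, group_a="old", group_b="young")
print(f"\nco-expression (detected panel genes per cell): KS D = {D:.3f}, p = {p:.2e}")
print("Old cells both express platelet genes more often (frequency), more")
print("strongly (dCt), and co-express more of the panel per cell (KS).")
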