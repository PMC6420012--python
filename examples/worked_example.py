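"""Two-point flux assay on the reference HepG2 labeling run.

A HepG2 culture (4.04e5 cells, mean cell volume 2.5 pL, 1 mL medium) was
switched to medium with 2 uM d4-Nam.  After 3 h the cells contain 276
pmol/1e6 cells of newly formed d3-NAD+ and the pre-existing d0-NAD+ pool has
dropped by 258 pmol/1e6 cells; the medium carries 48/264/4488 pmol/1e6 cells
of d3-/d0-/d4-Nam.
"""

from nadflux import CellContext, LabelingTimepoint, estimate_fluxes

context = CellContext(
    cell_count=4.04e5, cell_volume_pl=2.5, medium_volume_ml=1.0, d4_nam_conc_um=2.0
)
t0 = LabelingTimepoint(time_h=0.0, cell_d3_nad=0.0, cell_d0_nad=1437.0)
t3 = LabelingTimepoint(
    time_h=3.0,
    cell_d3_nad=276.0,
    cell_d0_nad=1179.0,
    medium_d3_nam=48.0,
    medium_d0_nam=264.0,
    medium_d4_nam=4488.0,
)

res = estimate_fluxes(t0, t3, context)

print(f"R_S (synthesis)  : {res.r_s:.1f} pmol/1e6 cells/h = {res.r_s_um_h:.1f} uM/h")
print(f"R_B (breakdown)  : {res.r_b:.1f} pmol/1e6 cells/h = {res.r_b_um_h:.1f} uM/h")
print(f"total NAD+       : {res.total_nad:.0f} pmol/1e6 cells")
print(f"NAD+ concentration: {res.nad_conc_um:.0f} uM")
print(f"NAD+ half-life   : {res.half_life_h:.1f} h")
rep = res.recycling_report
print(
    f"medium Nam: {100*rep.frac_d3_nam:.1f}% d3, {100*rep.frac_d0_nam:.1f}% d0, "
    f"{100*rep.frac_d4_nam:.1f}% d4 -> recycling check "
    f"{'passed' if rep.passed else 'FAILED'} (valid={res.valid})"
)
# The synthesis and breakdown rates nearly balance, so the NAD+ pool is close
# to steady state; the combined 6.5% breakdown-derived Nam confirms that
# tracer recycling is negligible over the 3-h window.
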