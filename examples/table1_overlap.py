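"""How many extracellular proteins does hESC-derived ECM share with each feeder ECM?

Loads the packaged comparison table (35 extracellular/cell-surface proteins
detected in HUES1 ECM across 7 samples) and counts, for each feeder-derived
ECM, the proteins also detected there. Percentages are relative to the 35
HUES1 proteins; the mouse-feeder summary uses the n-1 sample SD.
"""

from ecmprofiler import load_table1_fixture, shared_with_reference

matrix = load_table1_fixture()
main_rows = matrix.subset(
    proteins=list(matrix.protein_meta.index[~matrix.protein_meta["not_in_HUES1"]])
)

human = shared_with_reference(main_rows, "HUES1", ["ihPSF", "hPSF"])
for sample in ("ihPSF", "hPSF"):
    print(f"HUES1 shares {human.counts[sample]} proteins with {sample} "
          f"({human.percentages[sample]:.0f}% of {human.reference_size})")

mefs = ["CD1 P4", "CD1 P9", "MF1xCD1 P4", "MF1xCD1 P9"]
mouse = shared_with_reference(main_rows, "HUES1", mefs)
print(f"HUES1 vs the four MEF ECMs: {mouse.mean_count:.0f} +/- {mouse.sd_count:.1f} proteins "
      f"({mouse.mean_percentage:.0f}% +/- {mouse.sd_percentage:.1f}%)")
print("-> the supportive human feeder ECM (ihPSF) resembles hESC ECM far more "
      "than the unsupportive one (hPSF).")
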