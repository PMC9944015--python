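"""Protocol-level effective-dose table for the fixed-exposure scanner.

A scanner without tube current modulation delivers a fixed mAs and DAP per
protocol, so its dose table needs no patient data: each (FOV category, mode)
cell is the mean corrected DAP over its protocols times the age group's
conversion factor.  Standard-mode doses span 35.1-300 µSv, HR 238-527 µSv.
"""

from cbctdose import default_cf_table, default_device_registry, protocol_dose_table, round_sig

registry = default_device_registry()
table = protocol_dose_table(registry["accuitomo170"], default_cf_table())

print(f"{'age group':>10} {'FOV':>7} {'mode':>9} {'mean DAP':>9} {'dose [uSv]':>11}")
for cell in table:
    print(
        f"{cell.age_group.value:>10} {cell.fov_category.value:>7} {cell.mode.value:>9} "
        f"{round_sig(cell.mean_dap_dgycm2):>9} {round_sig(cell.mean_dose_usv):>11}"
    )
# Doses fall with age (smaller head -> larger organ fraction exposed in
# children) and rise with FOV size and with the high-resolution mode.
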