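"""Build the full 22-row risk table and the wheel-device data.

Each row is an access-time interval; the cell reports the interval's
lowest P(SBA) (its value at the upper bound — the conservative
convention), coloured salmon (< 0.90), light green ([0.90, 0.95)) or
dark green (>= 0.95).
"""

import sbarisk as sk

F = sk.onset_distribution("khambalia")
G = sk.latent_distribution("multiparous")
table = sk.build_risk_table("multiparous", F, G)

header = ["t (h)"] + table.column_keys
print("  ".join(f"{h:>9}" for h in header))
for iv, row in zip(table.intervals, table.cells):
    cells = "  ".join(f"{cell.display:>9}" for cell in row)
    print(f"{iv.label:>9}  {cells}")

sk.export_table(table, "risk_table_multiparous.csv")
sk.export_table(table, "risk_table_multiparous.json")
rings = sk.wheel_data(table)["rings"]
print(f"\nwrote CSV/JSON exports; wheel data has {len(rings)} concentric rings")
print(f"inner ring (move 4 weeks early) starts: {list(rings[-1]['values'].items())[:3]}")
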