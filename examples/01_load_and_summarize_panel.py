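"""Read a censored concentration panel and summarize its censoring.

Builds a tiny CSV in the on-disk dialect (numbers for observed values,
"<limit" for below-detection cells, empty for missing), loads it, and
prints the per-metal, per-group censoring summary.
"""

import tempfile
from pathlib import Path

from bayeslod import censoring_summary, load_panel

csv = """id,group,stage,Al,Hg
1,ASD,cord,5.1,<0.5
2,ASD,cord,3.4,0.8
3,control,cord,<1.0,0.4
4,control,cord,2.2,
"""

path = Path(tempfile.mkdtemp()) / "panel.csv"
path.write_text(csv)

panel = load_panel(path)
print(f"{panel.n} individuals x {panel.J} metals ({', '.join(panel.metals)})")
print(censoring_summary(panel).to_string(index=False))
# censoring_fraction is the share of a group's cells reported only as
# "< detection limit"; the missing Hg cell of individual 4 is interval-
# censored on [0, 10 x largest observed Hg] and counted under "interval".
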