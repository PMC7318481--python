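"""In-silico PCR with the degenerate cloning primers.

Reports the primers' degeneracies, confirms the forward primer encodes the
leader consensus start (MSDINAT) in every expansion, and amplifies a
synthetic MSDIN-bearing template with guaranteed binding sites. Writes
results/pcr.json.
"""

import json
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from msdin.pcr import (
    FORWARD_PRIMER,
    REVERSE_PRIMER,
    DegeneratePrimer,
    find_amplicons,
    primer_degeneracy,
)
from msdin.simulate import pcr_template

SEED = 1
results = Path(__file__).resolve().parent.parent / "results"
results.mkdir(exist_ok=True)

fwd = DegeneratePrimer("fwd", FORWARD_PRIMER)
translations = {str(Seq(e[:21]).translate()) for e in fwd.expansions()}

rng = np.random.default_rng(SEED)
template = pcr_template(FORWARD_PRIMER, REVERSE_PRIMER, rng)
amps = find_amplicons(template, FORWARD_PRIMER, REVERSE_PRIMER)

report = {
    "forward_primer": FORWARD_PRIMER,
    "reverse_primer": REVERSE_PRIMER,
    "forward_degeneracy": primer_degeneracy(FORWARD_PRIMER),
    "reverse_degeneracy": primer_degeneracy(REVERSE_PRIMER),
    "forward_translations": sorted(translations),
    "amplicons_on_synthetic_template": len(amps),
    "amplicon_length": amps[0].length if amps else None,
}
with open(results / "pcr.json", "w") as fh:
    json.dump(report, fh, indent=1)

print(f"Forward primer degeneracy {report['forward_degeneracy']} "
      f"(every expansion encodes {sorted(translations)}), reverse "
      f"{report['reverse_degeneracy']}.")
print(f"Synthetic template: {len(amps)} amplicon of "
      f"{report['amplicon_length']} nt.")
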