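"""Generate the synthetic input bundle every later stage consumes.

Writes promoter FASTA with planted TBS motifs plus truth tables,
occupancy, PBM probe, noise, turnover and cytometry tables under
results/synthetic/.
"""

import sys
from pathlib import Path

from tbpnoise.cli import main

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

if __name__ == "__main__":
    main(
        ["synth", "--seed", str(SEED), "--out", str(OUT)],
        standalone_mode=False,
        prog_name="tbpnoise",
    )
    print(f"wrote synthetic bundle (seed {SEED}) to {OUT}")
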