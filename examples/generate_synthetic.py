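"""Generate a small synthetic heart-sound dataset and inspect class structure.

Writes WAVs + manifest, then compares mean spectral energy in the murmur
band (150-400 Hz): unhealthy records should carry clearly more energy there,
since that band is where the simulated systolic murmur lives.
"""

import numpy as np

from heartpcg.synthetic import SynthConfig, band_energy, write_dataset

cfg = SynthConfig(n_healthy=12, n_unhealthy=6, duration=5.0, seed=0)
manifest, records = write_dataset(cfg, "scratch/synth_demo")
print(f"wrote {len(records)} records, manifest at {manifest}")

for label in ("healthy", "unhealthy"):
    energy = np.mean([
        band_energy(r.samples, r.rate, cfg.murmur_band)
        for r in records if r.label == label
    ])
    print(f"mean murmur-band energy, {label}: {energy:.2f}")
# The unhealthy mean should be one to two orders of magnitude larger:
# that spectral contrast is what the downstream classifier exploits.
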