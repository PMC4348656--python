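"""End-to-end synthetic binding experiment with occlusion correction.

Generates a liposome field whose per-particle protrusion count declines
linearly with diameter (lambda(D) = max(0, 8.4 - 0.2 D), ~5.4 rods at
15 nm, ~0.4 at 40 nm), projects every particle along a random viewing
axis, bins the visible counts by measured diameter, and divides each bin
by the visibility probability.  The corrected means recover the generating
law; the raw means underestimate it.
"""

import tempfile

import numpy as np

from lipocurv.pipeline import resolve_config, run_binding_pipeline

cfg = resolve_config(
    {
        "track": "binding",
        "seed": 1,
        "outdir": tempfile.mkdtemp(prefix="lipocurv_binding_"),
        "binding": {
            "n_particles": 10_000,
            "noise": {"cv": 0.0, "ar_mean": 1.0, "ar_sd": 0.0},
            "class_spec": {
                "label": "liposome",
                "diameter_law": ["normal", 18.5, 30.0],
                "diameter_bounds": [13.02, 23.87],
                "protrusion_length_law": [8.5, 0.0],
                "beta0": 8.4,
                "beta1": 0.2,
            },
        },
    }
)
res = run_binding_pipeline(cfg)
obs = res["observed_series"]
cor = res["corrected_series"]
print("bin center  n     observed  corrected  true lambda")
for c, o, v, n in zip(cor.bin_centers, obs.values, cor.values, cor.n_per_bin):
    if n >= 200:
        lam = max(0.0, 8.4 - 0.2 * c)
        print(f"{c:8.2f} {n:6d} {o:9.3f} {v:10.3f} {lam:11.3f}")
print(f"\nartifacts written to {res['outdir']}")
print("observed means are ~85-90% of the truth (hidden rods); corrected means match lambda")
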