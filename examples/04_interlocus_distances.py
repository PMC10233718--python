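"""Measure nanoscale inter-locus distances through the full imaging chain.

Three gene loci are placed at rigid 350 nm offsets (an equilateral
triangle) on a randomly oriented frame inside each nucleus, rendered with
channel-specific chromatic misalignment, detected, chromatically corrected
with transforms estimated from a simulated bead field, grouped into
triples, and summarized as gated 1D Gaussian peak fits with bootstrap
standard errors — the complete distance-analysis workflow.

Running the same analysis *without* the chromatic correction shows why the
bead registration step matters at this length scale.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nascentquant.colocalization import ColocParams, classify_cooccurrence
from nascentquant.detection import DetectionParams, detect_spots
from nascentquant.distances import pairwise_peak_report
from nascentquant.plotting import distance_histogram_plot, triangle_plot
from nascentquant.registration import (
    ChannelTransform,
    apply_transform_to_spots,
    identity_transform,
    register_bead_field,
)
from nascentquant.simulate import SimulationParams, render_bead_field, render_section

OUT = Path(__file__).parent / "output"
OUT.mkdir(exist_ok=True)

SEP = 350.0
OFFSETS = np.array([[0.0, 0.0, 0.0],
                    [0.0, 0.0, SEP],
                    [0.0, SEP * np.sqrt(3) / 2, SEP / 2]])
CENTER = (127.5, 127.5)
TRUE_TR = {
    "red": ChannelTransform(channel="red", dx=1.5, dy=-1.0,
                            rotation=np.deg2rad(0.3), scale=1.002, center=CENTER),
    "green": ChannelTransform(channel="green", dx=-1.2, dy=0.8,
                              rotation=np.deg2rad(-0.2), scale=0.998, center=CENTER),
}
DET = DetectionParams(min_amplitude=200.0)
N_SECTIONS = 8

# 1. calibrate the chromatic correction from a bead field
bead_stack, _ = render_bead_field(TRUE_TR, n_beads=50,
                                  channels=("farred", "red", "green"), seed=7)
est_tr = register_bead_field(bead_stack, "farred", DET)
for ch in ("red", "green"):
    print(f"{ch}: estimated shift ({est_tr[ch].dx:+.2f}, {est_tr[ch].dy:+.2f}) px, "
          f"residual {est_tr[ch].residual_nm:.1f} nm")

# 2. image sections with bright spots and known 350 nm geometry
channels = ("farred", "red", "green")
pools = {"corrected": {ch: [] for ch in channels},
         "uncorrected": {ch: [] for ch in channels}}
for s in range(N_SECTIONS):
    params = SimulationParams(burst_probs=(0.95, 0.95, 0.95), n_cells=15,
                              locus_offsets=OFFSETS, spot_amplitude=800.0,
                              chromatic_transforms=TRUE_TR, seed=800 + s)
    stack, _ = render_section(params)
    for ch in channels:
        t = detect_spots(stack, ch, DET)
        t = t[t["accepted"]].reset_index(drop=True)
        for name, tr in (("corrected", est_tr[ch]),
                         ("uncorrected", identity_transform(ch, CENTER))):
            frame = apply_transform_to_spots(t, tr, stack)
            frame["x_nm"] += s * 1e6  # keep sections apart in the pooled frame
            pools[name][ch].append(frame)

# 3. group into triples and fit the pairwise distance peaks
for name in ("corrected", "uncorrected"):
    tables = {ch: pd.concat(v, ignore_index=True) for ch, v in pools[name].items()}
    records, _ = classify_cooccurrence(tables, ColocParams(frame="3d"))
    rep = pairwise_peak_report(tables, records, list(channels),
                               n_bootstrap=300, seed=0)
    print(f"\n{name} (generative separation {SEP:.0f} nm):")
    for pair, dd in rep["pairs"].items():
        f = dd.fit
        print(f"  {pair[0]}-{pair[1]}: n={f.n}, "
              f"peak {f.peak:.1f} +- {f.se:.1f} nm ({f.method})")
    if name == "corrected":
        for pair, dd in rep["pairs"].items():
            distance_histogram_plot(dd, OUT / f"dist_{pair[0]}_{pair[1]}.png")
        triangle_plot(rep["triangle"], OUT / "triangle.png")
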