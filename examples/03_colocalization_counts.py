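"""Classify single/double/triple nascent-transcription co-occurrence.

A nascent spot marks a gene bursting in a cell. Spots from different
channels whose centres fall within 500 nm are grouped into one record by
greedy closest-first matching (triples require mutual proximity of all
three members). Counting singles, doubles and triples across a section
asks: do these genes burst in the same cells more often than chance?

The chance baseline comes from `expected_random_coloc`: model (a) is
cell-level independence (n_A * n_B / C co-active cells expected), model (b)
multiplies by the geometric probability that two independently placed
nuclear spots land within the radius, and carries a 99% predictive interval
for the observed count under the null.

Positive coupling in the simulator should push the observed count above
that interval; here we compare coupled and independent cohorts.
"""

from pathlib import Path

from nascentquant.colocalization import (
    ColocParams,
    classify_cooccurrence,
    expected_random_coloc,
)
from nascentquant.simulate import SimulationParams, simulate_spot_fields

OUT = Path(__file__).parent / "output"
OUT.mkdir(exist_ok=True)

N_CELLS = 4000

for label, coupling in (("independent", 1.0), ("co-regulated", 1.6)):
    params = SimulationParams(genes=("geneA", "geneB"), burst_probs=(0.4, 0.4),
                              coupling=coupling, n_cells=N_CELLS,
                              placement="grid", seed=3)
    tables, truth = simulate_spot_fields(params, seed=3)
    cp = ColocParams(frame="2d")
    records, summary = classify_cooccurrence(tables, cp)
    summary.to_csv(OUT / f"coloc_summary_{label}.csv")
    observed = int(summary.loc["farred", "double:farred,red"])
    exp = expected_random_coloc(
        {ch: int(summary.loc[ch, "total"]) for ch in ("farred", "red")},
        n_cells=N_CELLS, params=cp, seed=4)
    mb = exp["model_b"]["double:farred,red"]
    lo, hi = mb["interval"]
    verdict = ("ABOVE the null interval -> co-regulation detected"
               if observed > hi else
               "inside the null interval -> consistent with chance")
    print(f"{label} (coupling {coupling}):")
    print(f"  spots: farred {summary.loc['farred', 'total']}, "
          f"red {summary.loc['red', 'total']} over {N_CELLS} cells")
    print(f"  observed doubles {observed}; "
          f"chance expectation {mb['expected']:.1f} "
          f"(99% null interval [{lo:.0f}, {hi:.0f}])")
    print(f"  -> {verdict}")
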