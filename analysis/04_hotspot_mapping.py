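"""Map ESV hot and cold spots on the 2 km grid with Getis–Ord Gi*.

Reads results/cells.csv (from 03), classifies each cell by its Gi* standard
deviate, and writes results/hotspots.csv plus a category census.
"""

import os

import pandas as pd

from esvscape.spatial import build_weights, gi_star

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cells = pd.read_csv(os.path.join(OUT, "cells.csv"))
    w = build_weights(cells, "distance_band", 3000.0, include_self=True)
    hot = gi_star(cells, w, "esv_per_area")
    hot.to_csv(os.path.join(OUT, "hotspots.csv"), index=False, float_format="%.10g")
    census = hot["category"].value_counts()
    print(f"Gi* on {len(cells)} cells (band 3000 m):")
    print(census.to_string())
    n_sig = (hot["category"] != "ns").sum()
    print(f"{n_sig} cells ({100 * n_sig / len(hot):.1f}%) in significant clusters")


if __name__ == "__main__":
    main()
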