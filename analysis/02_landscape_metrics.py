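"""Compute the six landscape predictors per window x year from the maps.

Reads the gridded class maps and hedgerow GeoJSON written by
01_simulate_study.py, computes compositional heterogeneity (Shannon),
configurational heterogeneity (-ln mean patch area), grassland amount and
isolation, hedgerow amount and isolation, screens predictor correlations
(Spearman, threshold 0.87), and writes the tidy predictor table under
results/.
"""

from pathlib import Path

from traitscape.io import align_networks, read_map_csv, read_networks_geojson
from traitscape.landscape import compute_landscape_variables, predictor_correlations

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
CELL_SIZE = 10.0


def main() -> None:
    networks = read_networks_geojson(RUN_DIR / "hedgerows.geojson")
    maps = {}
    for path in sorted((RUN_DIR / "maps").glob("*.csv")):
        window, year = path.stem.split("_", 1)
        maps[(window, year)] = read_map_csv(path, CELL_SIZE, window, year)

    lv = compute_landscape_variables(maps, align_networks(maps, networks), snap_tol=0.5)
    RESULTS.mkdir(exist_ok=True)
    lv.to_csv(RESULTS / "landscape_variables.csv", index=False)

    print(f"{lv['window'].nunique()} windows x {lv['year'].nunique()} years")
    for year in sorted(lv["year"].unique()):
        corr, flags = predictor_correlations(lv, year=year)
        worst = corr.abs().where(~(corr.abs() >= 1.0)).max().max()
        print(f"  {year:>12}: max |Spearman rho| between predictors = {worst:.2f}")
        for a, b, rho in flags:
            print(f"    screen flag: rho({a}, {b}) = {rho:.2f}")
    print(f"predictor table -> {RESULTS / 'landscape_variables.csv'}")


if __name__ == "__main__":
    main()
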