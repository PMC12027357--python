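"""Full preprocessing x selection comparison for SSC and firmness.

Per (trait, storage temperature): Kennard-Stone 3:1 split, then raw
spectra, each preprocessing alone, and every preprocessing+selection
combination.  Writes results/regression_report.csv.
"""

from pathlib import Path

from nirapple import generate_dataset
from nirapple.pipeline import RunConfig, run_regression_grid, write_report

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = RunConfig(seed=SEED, uve_n_submodels=40)
    dataset = generate_dataset(seed=SEED)
    report = run_regression_grid(config, dataset)
    out = ROOT / "results" / "regression_report.csv"
    write_report(report, out)
    print(f"wrote {out} ({len(report)} rows)")

    for (trait, temp), grp in report.groupby(["quality_parameter", "temperature"]):
        ok = grp[grp["error"] == ""]
        best = ok.loc[ok["rp"].idxmax()]
        print(f"  {trait:>8} @ {temp:>4.0f} degC: best Rp {best['rp']:.3f} "
              f"(RMSEP {best['rmsep']:.3f}, {best['latent_variables']:.0f} LV) "
              f"with {best['treatment']}")


if __name__ == "__main__":
    main()
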