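"""Significance tests on where and when deaths occur.

Runs the control-resampling binomial GLM (actual deaths vs one simulated
death day per never-dead control; likelihood-ratio tests for stage, age
and their interaction), the pooled-age chi-square of death frequencies,
and one-way ANOVAs of age-at-death and latitude-at-death by stage.
Writes inference_tests.json.
"""

import argparse
from pathlib import Path

from fullcycle.pipeline import default_run_config, run_tests
from fullcycle.simulate import read_tracking_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = default_run_config(seed=args.seed)
    records = read_tracking_csv(Path(args.out) / "tracking.csv")
    report = run_tests(cfg, records, args.out)

    print(f"{report['n_deaths']} deaths vs {report['n_controls']} controls "
          f"({report['n_excluded_short_tracking']} excluded for short tracking)")
    for term, res in report["glm"]["terms"].items():
        print(f"  GLM {term}: LRT={res['lrt']:.2f}, df={res['df']}, p={res['p']:.4f}")
    chi = report["chi2_age_stage"]
    print(f"  chi-square age x stage: chi2={chi['chi2']:.2f}, df={chi['df']}, "
          f"p={chi['p']:.4f}")
    for key in ("anova_age_at_death", "anova_latitude"):
        res = report[key]
        if "error" in res:
            print(f"  {key}: {res['error']}")
        else:
            print(f"  {key}: F({res['df1']},{res['df2']})={res['F']:.2f}, "
                  f"p={res['p']:.4f}")


if __name__ == "__main__":
    main()
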