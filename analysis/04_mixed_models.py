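#!/usr/bin/env python
"""Random-intercept mixed models: concentration, discharge trend, AMA interaction.

Fits the session-level models the scores support: condition-mean response time
on self-reported concentration (per group), and, for patients, on the
days-to-discharge countdown with its interaction with leaving Against Medical
Advice.  The generating slopes are known (they are config fields), so each
table row can be read as a parameter-recovery check.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from voicestroop.config import default_config
from voicestroop.pipeline import write_csv
from voicestroop.scoring import score_cohort
from voicestroop.stats import fit_random_intercept
from voicestroop.synthesize import simulate_cohort

SEED = 20230304


def main() -> None:
    cfg = default_config(SEED)
    cohort = simulate_cohort(cfg)
    groups = cohort.participants.set_index("participant_id")["group"]
    scores, _ = score_cohort(cohort.schedules_frame(), cohort.events_frame(), groups)
    cov = cohort.covariates_frame().drop(columns=["group"])
    scores = scores.merge(cov, on=["participant_id", "session_index"])
    scores["ama"] = scores["ama_flag"].astype(float)

    rows = []
    for g, sub in scores.groupby("group"):
        for outcome in ("mean_rt_congruent", "mean_rt_neutral", "mean_rt_incongruent"):
            res = fit_random_intercept(sub, outcome, ["concentration"])
            rows.append(
                {
                    "group": g, "outcome": outcome, "term": "concentration",
                    "B": res.params["concentration"], "SE": res.bse["concentration"],
                    "t": res.tvalues["concentration"], "p": res.pvalues["concentration"],
                    "generating": cfg.group_params(g).beta_concentration,
                    "lrt_chi2": res.chi_square_vs_null, "lrt_p": res.p_value,
                }
            )

    pt = scores[scores.group == "patient"]
    res = fit_random_intercept(
        pt, "mean_rt_incongruent", ["days_to_discharge", "ama"],
        interaction=("days_to_discharge", "ama"),
    )
    for term, gen in (
        ("days_to_discharge", cfg.patient.beta_days),
        ("days_to_discharge:ama", cfg.patient.beta_days_ama),
    ):
        rows.append(
            {
                "group": "patient", "outcome": "mean_rt_incongruent", "term": term,
                "B": res.params[term], "SE": res.bse[term],
                "t": res.tvalues[term], "p": res.pvalues[term],
                "generating": gen, "lrt_chi2": res.chi_square_vs_null,
                "lrt_p": res.p_value,
            }
        )

    table = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_csv(table, out / "04_mixed_models.csv", cfg.config_hash())
    pd.set_option("display.float_format", lambda v: f"{v:.5g}")
    print(table.to_string(index=False))
    print("\nEach B should sit within ~2 SE of its generating value.")


if __name__ == "__main__":
    main()
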