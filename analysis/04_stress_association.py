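#!/usr/bin/env python
"""Association of the deletion with expression and oxidative-stress
survival in a simulated inbred-line panel.

Emulates a DGRP-style panel (150 lines, both sexes, two expression
replicates per line x sex, survival of replicate flies on MSB and
paraquat). True effects follow the study conditions: expression folds
1.33 (F) / 1.40 (M), male-biased expression 1.67-fold, and a protective
deletion hazard ratio of 0.6 on MSB only. Reports per-sex t-tests and
variance explained, expression-survival Spearman correlations, and Cox
proportional-hazards fits per agent.

Writes results/association_panel.tsv and results/association_summary.json.
"""

from pathlib import Path

import warnings

from mtna import assoc, qpcr, simulate
from mtna.genotyping import DELETION, NON_DELETION
from mtna.io import write_json, write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main():
    OUT.mkdir(exist_ok=True)
    config = simulate.SimConfig(seed=SEED, p_del=112 / 161)
    panel = assoc.prepare_line_panel(simulate.simulate_survival(config))
    write_tsv(OUT / "association_panel.tsv", panel, dict(seed=SEED))

    lines = panel.drop_duplicates(["line_id", "sex"])
    results = {}
    print("Expression (log2 array scale) by genotype:")
    for sex, grp in lines.groupby("sex"):
        tt = assoc.expression_ttest(
            grp.loc[grp.genotype == DELETION, "expression"],
            grp.loc[grp.genotype == NON_DELETION, "expression"],
        )
        tt["variance_explained_pct"] = 100 * qpcr.variance_explained(
            grp["expression"], grp["genotype"]
        )
        results[f"expression_{sex}"] = {k: round(float(v), 4) for k, v in tt.items()}
        print(
            f"  {sex}: {tt['fold']:.2f}-fold higher in deletion lines "
            f"(t = {tt['t']:.2f}, P = {tt['p']:.2g}); "
            f"indel explains {tt['variance_explained_pct']:.1f}% of variance"
        )
    sex_fold = 2 ** (
        lines.loc[lines.sex == "M", "expression"].mean()
        - lines.loc[lines.sex == "F", "expression"].mean()
    )
    results["male_female_fold"] = round(float(sex_fold), 3)
    print(f"  male/female expression ratio: {sex_fold:.2f}-fold (truth 1.67)")

    # paper-style model: sex + genotype + line factors (genotype is constant
    # within line, so one line indicator is aliased and dropped); the
    # genotype test below comes from the reduced sex + genotype model
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        contrast = assoc.agent_contrast(panel, line_col=None)
        full = assoc.agent_contrast(
            panel[panel.agent == "MSB"], line_col="line_id", line_mode="factor"
        )
    results["agents"] = contrast.round(5).to_dict("records")
    results["msb_full_line_factor_model"] = full.round(5).to_dict("records")
    write_json(OUT / "association_summary.json", results)

    print("Survival associations per agent (deletion hazard ratio; truth: "
          "0.6 on MSB, 1.0 on paraquat):")
    for row in contrast.itertuples():
        print(
            f"  {row.agent}: HR = {row.genotype_hazard_ratio:.2f} "
            f"(P = {row.genotype_p:.2g}); expression-survival Spearman "
            f"rho = {row.spearman_rho:.2f} (P = {row.spearman_p:.2g})"
        )


if __name__ == "__main__":
    main()
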