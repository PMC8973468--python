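"""Test each feature for a difficulty effect with subject-level mixed models.

For every feature: REML linear mixed model (difficulty fixed; subject
random intercept plus, where identifiable, per-level random effects),
likelihood-ratio test of the difficulty effect (ML refits, chi-square df 2),
Tukey-style pairwise contrasts with a single-step max-|z| family
adjustment, and a refit after screening |standardised residual| > 3.

Outputs: results/analysis/lrt.csv, contrasts.csv
"""

from pathlib import Path

import pandas as pd

from pupilload.stats import run_feature_analysis

OUT = Path("results/analysis")


def main() -> None:
    feats = pd.read_csv(OUT / "features.csv")
    analysis = run_feature_analysis(feats)

    lrt = analysis.lrt_frame()
    lrt.to_csv(OUT / "lrt.csv", index=False, float_format="%.6g")
    contrasts = analysis.contrast_frame()
    contrasts.to_csv(OUT / "contrasts.csv", index=False, float_format="%.6g")

    print("Likelihood-ratio tests (difficulty effect, df = 2):")
    print(lrt.assign(p=lrt.p.map("{:.2e}".format)).to_string(index=False))
    n_sig = (lrt.loc[lrt.feature != "BLPS", "p"] < 0.001).sum()
    print(f"\n{n_sig}/6 dilation features significant at p < 0.001; "
          f"BLPS p = {float(lrt.loc[lrt.feature == 'BLPS', 'p'].iloc[0]):.2f} "
          "(baseline carries no difficulty signal, as designed).")
    print(f"\nInfluence screening flagged {analysis.n_flagged} observations "
          "(|standardised residual| > 3); 'final' contrasts refit without them.")
    show = contrasts.query("feature == 'MPDC' and stage == 'initial'")
    print("\nMPDC pairwise contrasts (initial model):")
    print(show[["contrast", "estimate", "std_error", "p_adjusted"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
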