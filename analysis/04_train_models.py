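"""Fit the six regression algorithms on each feature scheme and evaluate.

Samples are split 7:3 (stratified by growth stage) into modeling and
validation sets; each (scheme, algorithm) pair is fit pooled and per stage.
The tidy accuracy matrix (R2, RMSE, NRMSE) goes to results/model_results.csv.
"""

from canagb.estimation import SplitSpec, run_matrix
from canagb.pipeline import select_schemes, stage_seed
from _campaign import DEFAULT_SEED, RESULTS, campaign_features


def main(seed: int = DEFAULT_SEED) -> None:
    spectral, texture = campaign_features(seed)
    schemes, _ = select_schemes(spectral, texture)
    merged = spectral.merge(
        texture.drop(columns=["agb", "treatment_id"]), on=["plot_id", "stage"]
    )
    frame, _ = run_matrix(
        merged, schemes, split_spec=SplitSpec(seed=stage_seed(seed, "split"))
    )
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "model_results.csv", index=False, float_format="%.6g")

    ok = frame[(frame["status"] == "ok") & (frame["stage"] == "pooled")]
    print("pooled validation accuracy (180 samples, 126/54 split):")
    print(
        ok.pivot(index="algorithm", columns="scheme", values="R2")
        .round(3)
        .to_string()
    )
    best = ok.loc[ok["R2"].idxmax()]
    print(
        f"best: {best['algorithm']} on {best['scheme']} — R2 {best['R2']:.3f}, "
        f"RMSE {best['RMSE_kg_ha']:.0f} kg/ha, NRMSE {best['NRMSE_pct']:.1f}%"
    )
    print("wrote results/model_results.csv")


if __name__ == "__main__":
    main()
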