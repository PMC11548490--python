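"""Extract the spectral and texture feature tables for the campaign.

Per sample: 138 narrowband plot-mean reflectances + 21 vegetation indices
(159 spectral features) and six co-occurrence statistics per band and per VI
image (954 texture features).  The full tables are cached under
scratch/analysis/; a compact per-group correlation summary goes to
results/feature_correlations.csv.
"""

import pandas as pd

from canagb.pipeline import feature_columns
from canagb.selection import correlate
from _campaign import DEFAULT_SEED, RESULTS, campaign_features


def main(seed: int = DEFAULT_SEED) -> None:
    spectral, texture = campaign_features(seed)
    n_spec = len(feature_columns(spectral))
    n_tex = len(feature_columns(texture))
    print(f"{len(spectral)} samples; {n_spec} spectral + {n_tex} texture features")

    report = pd.concat(
        [
            correlate(spectral, features=feature_columns(spectral)),
            correlate(texture, features=feature_columns(texture)),
        ],
        ignore_index=True,
    )
    summary = (
        report.groupby("group")["abs_r"]
        .agg(["count", "mean", "min", "max"])
        .rename(columns={"count": "n_features"})
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "feature_correlations.csv", float_format="%.4f")
    print("|r| with AGB by feature group:")
    print(summary.round(3).to_string())
    print("wrote results/feature_correlations.csv")


if __name__ == "__main__":
    main()
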