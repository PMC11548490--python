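"""Screen features against biomass and assemble the three feature schemes.

Stage one keeps features with |Pearson r| >= 0.6 against AGB; stage two
greedily drops features correlated above 0.9 with an already-kept feature.
The surviving spectral and texture variables form the spectra, texture, and
spectra-texture schemes written to results/schemes.json.
"""

from canagb.pipeline import select_schemes
from canagb.selection import save_schemes
from _campaign import DEFAULT_SEED, RESULTS, campaign_features


def main(seed: int = DEFAULT_SEED) -> None:
    spectral, texture = campaign_features(seed)
    schemes, report = select_schemes(spectral, texture)
    retained = report[report["abs_r"] >= 0.6]
    print(f"screen at |r| >= 0.6: {len(retained)} of {len(report)} features survive")
    for name, scheme in schemes.items():
        print(f"  {name}: {len(scheme)} variables")
    print("spectra scheme:", ", ".join(schemes["spectra"].features[:8]), "...")
    RESULTS.mkdir(exist_ok=True)
    save_schemes(schemes, RESULTS / "schemes.json")
    print("wrote results/schemes.json")


if __name__ == "__main__":
    main()
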