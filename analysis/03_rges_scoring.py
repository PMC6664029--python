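"""Score every gold drug profile against the disease signature (RGES),
summarize per compound relative to the 10 uM / 24 h reference condition
(sRGES), and contrast RGES across biological conditions.

Reads results/inputs/ and results/signature.tsv; writes results/rges.tsv
and results/srges.tsv.
"""

from pathlib import Path

from revsig import io
from revsig.signature_scoring import (condition_contrast, score_profiles,
                                      summarize_rges)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    signature = io.read_signature(RESULTS / "signature.tsv")
    profiles = io.read_profiles(RESULTS / "inputs")
    n_gold = sum(p.is_gold for p in profiles)
    print(f"{n_gold}/{len(profiles)} profiles flagged gold and scored")

    rges = score_profiles(profiles, signature)
    rges.to_csv(RESULTS / "rges.tsv", sep="\t", index=False,
                float_format="%.10g")
    srges = summarize_rges(rges)
    srges.to_csv(RESULTS / "srges.tsv", sep="\t", index=False,
                 float_format="%.10g")

    print("strongest reversers (lowest sRGES):")
    for _, r in srges.head(5).iterrows():
        print(f"  {r['compound']}: sRGES {r['srges']:+.3f} "
              f"({r['n_profiles']} profiles)")

    for factor, label in (("dose", "dose < 10 uM vs >= 10 uM"),
                          ("duration", "duration < 24 h vs >= 24 h")):
        res = condition_contrast(rges, factor)
        print(f"RGES contrast, {label}: rank-test p = {res.p_value:.3g} "
              f"({res.n_low} vs {res.n_high} profiles)")


if __name__ == "__main__":
    main()
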