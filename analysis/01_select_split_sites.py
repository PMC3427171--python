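#!/usr/bin/env python
"""Select candidate split sites from a CP-viability score profile.

Generates a synthetic 137-residue intein-like profile with favorable local
maxima planted at residues 12, 36 and 102 (the two N-proximal engineered
sites plus the naturally occurring one), then runs the selection chain:
local maxima -> favorability thresholds (>0.7 favorable, <0.5 unfavorable)
-> active-site separation filter (catalytic residues 1 and 137, min 10
residues) -> ranking with N-terminal-half preference.

Writes results/split_sites.tsv and prints the ranked candidates.
"""

import pandas as pd

from splitscan.simulate import gen_score_profile
from splitscan.sites import classify_sites, rank_candidates

OUT = "results/split_sites.tsv"


def main() -> None:
    profile = gen_score_profile(
        n=137,
        peaks=[(12, 0.55, 3.0), (36, 0.55, 3.0), (102, 0.5, 3.0)],
        baseline=0.3,
        noise_sd=0.03,
        seed=20120824,
        protein_id="npu_synthetic",
    )
    klasses = {c.site: c.klass for c in classify_sites(profile)}
    candidates = rank_candidates(profile, active_sites=[1, 137], min_sep=10)

    rows = [
        {
            "rank": c.rank,
            "site": c.site,
            "score": round(c.score, 3),
            "klass": klasses[c.site],
            "seq_sep_active": c.seq_sep_active,
            "n_terminal_half": c.in_n_half,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT, sep="\t", index=False)

    print(f"{len(df)} favorable local-maximum split sites pass the filters:")
    print(df.to_string(index=False))
    print(
        "\nThe two N-terminal-half sites (12, 36) rank ahead of the "
        "C-terminal site 102 at comparable scores, matching the selection "
        f"rationale.  Table written to {OUT}."
    )


if __name__ == "__main__":
    main()
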