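"""Mouse-human syntenic copy-number concordance.

Mouse CNA-positive regions are paired with their human homologues through an
explicit homology map; a pair is concordant when the same CNA type exceeds a
5% carrier-frequency threshold in human samples (strictly). Per CNA type the
concordant/discordant tallies against a caller-supplied background stratum
form a 2x2 contingency table tested with the two-tailed Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FREQ_THRESHOLD = 0.05


def map_homologues(
    mouse: pd.DataFrame, homology: pd.DataFrame, human: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Pair mouse CNA regions with their human homologues.

    ``homology`` has columns mouse_key, human_key (a mouse region may map to
    several human regions; all pairs are retained). Region keys are the
    ``name`` column when present, else ``chrom:start-end``. Returns the pair
    table and the list of unmapped mouse keys.
    """
    mouse = mouse.copy()
    human = human.copy()
    mouse["key"] = _region_keys(mouse)
    human["key"] = _region_keys(human)
    human_keys = set(human["key"])
    dangling = set(homology["human_key"]) - human_keys
    if dangling:
        raise KeyError(f"homology map references unknown human regions: {sorted(dangling)[:5]}")
    dangling_m = set(homology["mouse_key"]) - set(mouse["key"])
    if dangling_m:
        raise KeyError(f"homology map references unknown mouse regions: {sorted(dangling_m)[:5]}")

    pairs = (
        mouse.merge(homology, left_on="key", right_on="mouse_key")
        .merge(
            human.add_prefix("human_"),
            left_on="human_key",
            right_on="human_key",
            suffixes=("", "_h"),
        )
    )
    unmapped = sorted(set(mouse["key"]) - set(homology["mouse_key"]))
    return pairs, unmapped


def _region_keys(df: pd.DataFrame) -> pd.Series:
    if "name" in df.columns:
        return df["name"].astype(str)
    return df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)


@dataclass
class ContingencyTable2x2:
    """Counts: rows = mouse CNA-positive vs background, cols = human frequency > threshold vs not."""

    a: int  # CNA-positive & concordant
    b: int  # CNA-positive & discordant
    c: int  # background & above threshold
    d: int  # background & not

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def concordance_flags(
    pairs: pd.DataFrame,
    cna_type: str,
    threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> pd.Series:
    """Per pair: does the human homologue carry the same CNA type above threshold?

    ``pairs`` rows need mouse ``cna_type`` and human ``human_frequency`` /
    ``human_cna_type``; a missing human frequency counts as 0. "Exceeds" is
    strict (frequency > threshold).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold outside [0, 1]")
    sub = pairs[pairs["cna_type"] == cna_type]
    same_type = sub["human_cna_type"] == cna_type
    freq = sub["human_frequency"].fillna(0.0)
    return (same_type & (freq > threshold)).rename("concordant")


def concordance_table(
    pairs: pd.DataFrame,
    background: pd.DataFrame,
    cna_type: str,
    threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> ContingencyTable2x2:
    """Tally concordance of mouse CNA regions of one type vs a background stratum.

    The background table is subjected to the same frequency rule; the paper's
    procedure leaves the comparison stratum to the caller (e.g. permuted or
    non-CNA regions).
    """
    fg = concordance_flags(pairs, cna_type, threshold)
    bg = concordance_flags(background, cna_type, threshold)
    return ContingencyTable2x2(
        a=int(fg.sum()),
        b=int((~fg).sum()),
        c=int(bg.sum()),
        d=int((~bg).sum()),
    )


def carrier_frequency(
    region: pd.Series, sample_calls: pd.DataFrame, cna_type: str
) -> float:
    """Fraction of human samples with a same-type call overlapping >= 1 bp.

    ``sample_calls`` columns: sample, chrom, start, end, cna_type. Used when
    per-region frequencies are not supplied directly.
    """
    calls = sample_calls[
        (sample_calls["cna_type"] == cna_type)
        & (sample_calls["chrom"] == region["chrom"])
        & (sample_calls["start"] < region["end"])
        & (sample_calls["end"] > region["start"])
    ]
    n_samples = sample_calls["sample"].nunique()
    if n_samples == 0:
        raise ValueError("no samples in call table")
    return calls["sample"].nunique() / n_samples


def fisher_exact(tbl: ContingencyTable2x2) -> float:
    """Two-tailed Fisher's exact p-value (point-probability method).

    Sums hypergeometric probabilities of every table with the same margins
    whose probability does not exceed that of the observed table.
    """
    _, p = stats.fisher_exact(tbl.as_array(), alternative="two-sided")
    return float(min(p, 1.0))
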