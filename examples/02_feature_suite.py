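"""Compute the 15-feature vector for synthetic segments and compare classes.

Shows the time-domain variability indices (STV, DELTA, II, LTI) computed on
the 2.5-s interbeat-interval series, the Welch band powers, approximate
entropy, the excursion-excluding baseline, and detected event counts — and
how the default class contrast (halved variability, fewer accelerations in
the pathological class) shows up in the numbers.
"""

import numpy as np

from fhrfusion.features import FEATURE_NAMES, extract_features
from fhrfusion.pipeline import features_table, segments_from_records
from fhrfusion.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(), n_per_class=10, seed=3)
segments = segments_from_records(ds.records)
table = features_table(segments)

print(f"{len(segments)} segments -> {table.shape[0]} feature rows\n")

one = extract_features(segments[0])
print(f"example segment {segments[0].segment_id} (label {segments[0].label}):")
for name, value in zip(FEATURE_NAMES, one.to_array()):
    print(f"  {name:>18s} = {value:10.4f}")

print("\nper-class feature means (healthy=0, pathological=1):")
means = table.groupby("label")[FEATURE_NAMES].mean()
for name in ("STV", "DELTA", "LTI", "LF", "MF", "HF", "ApEn",
             "small_accels", "large_accels", "decels"):
    h, p = means.loc[0, name], means.loc[1, name]
    print(f"  {name:>14s}: healthy {h:8.3f}   pathological {p:8.3f}")

print("\nreduced variability and reactivity in the pathological class is")
print("visible directly in STV/DELTA/LTI, the band powers and accelerations.")
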