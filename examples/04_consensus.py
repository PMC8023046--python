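"""Gold-standard consensus over specialist triples with expert review.

Every recording is rated independently by three specialists; unanimous
triples enter the gold standard directly, 2-vs-1 splits go to the expert
group, and triples with no definite majority are rejected.
"""

import pandas as pd

from lungsound.consensus import build_gold_standard

ratings = pd.DataFrame({
    "recording_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3,
    "rater_id": ["s1", "s2", "s3"] * 4,
    "label": ["crackle", "crackle", "crackle",          # unanimous
              "wheeze", "wheeze", "normal",             # 2-vs-1 split
              "crackle", "wheeze", "normal",            # fully inconsistent
              "normal", "indeterminate", "indeterminate"],  # no definite majority
})
experts = pd.DataFrame({"recording_id": ["b"], "expert_label": ["wheeze"]})

gs = build_gold_standard(ratings, experts)
print(gs.to_string(index=False))
print("\nOnly 'a' (unanimous) and 'b' (expert-confirmed) enter the gold "
      "standard; 'c' and 'd' are rejected by the consensus rules.")
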