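"""Compare the four coverage-curve similarity metrics on toy curves.

A silencer leaves a reporter curve that no longer follows the input
curve's shape; windows whose score on the common higher-is-more-similar
scale exceeds 0.9 are discarded by the caller. Here the reporter curve is
a scaled-down copy of the input inside a "silencer" and identical outside.
"""

import numpy as np

from fastnr import CoverageCurve, compute_similarity

x = np.arange(60, dtype=float)
insert = 100.0 + 20.0 * np.sin(x / 6.0)
reporter = insert.copy()
reporter[20:40] *= 0.1  # 90% depletion in the middle third

cu = CoverageCurve(x, reporter)
cv = CoverageCurve(x, insert)
print("metric     raw_value  score  kept(score<=0.9)")
for metric in ("cosine", "euclidean", "pearson", "gradient"):
    res = compute_similarity(cu, cv, metric)
    print(
        f"{metric:<10} {res.raw_value:9.3f} {res.similarity_score:6.3f}  "
        f"{res.similarity_score <= 0.9}"
    )
res = compute_similarity(cu, cv, "cosine")
print(
    f"\nsimilarity index -log2(cosine distance) = {res.similarity_index:.2f}; "
    "small index = dissimilar curves = silencer-like window."
)
ident = compute_similarity(cv, cv, "cosine")
print(
    f"identical curves score {ident.similarity_score:.3f} -> discarded: "
    "a window that mirrors its input is not a silencer."
)
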