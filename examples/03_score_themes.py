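"""Score every corpus path against labeled flagship sets.

After clusters are labeled with themes (here: by the generator's gold
labels standing in for the human annotation step), every corpus path gets
a raw support per theme — the number of (entity pair, flagship path)
co-occurrences — and a normalized score that sums to 1 across themes.
"""

from litnet.pipeline import run_synthetic_pipeline
from litnet.simulate import SyntheticConfig, generate_theme_corpus

corpus = generate_theme_corpus(SyntheticConfig(n_themes=3, noise=0.05, seed=3))
clustering, scored, gold = run_synthetic_pipeline(corpus, n_runs=30, base_seed=3)

print(f"flagship sets: { {t: len(s) for t, s in scored.flagships.items()} }")
print(f"{len(scored.scores)} paths received scores\n")
sample = scored.scores.head(4)
print(sample.round(3).to_string())
print()
for path in sample.index:
    top = sample.loc[path].idxmax().replace("score_", "")
    print(f"argmax {top}  (gold {gold.path_theme[path]})  {path[:46]}...")

# A path's score vector is its theme profile; the dominant entry says
# which relationship class the sentences using this grammatical pattern
# usually describe.  Paths that never co-occur with any flagship path are
# excluded (they cannot be scored by co-occurrence).
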