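"""Write and read the two-part network distribution files.

Part I maps dependency paths to per-theme supports and flagship flags;
Part II holds the sentence-level records, sorted by entity pair so all
sentences about the same two entities are adjacent.
"""

import tempfile
from pathlib import Path

from litnet.netio import read_part1, read_part2, write_part1, write_part2
from litnet.pipeline import run_synthetic_pipeline
from litnet.schema import load_schema
from litnet.simulate import SyntheticConfig, generate_theme_corpus
from litnet.pipeline import extract_synthetic

corpus = generate_theme_corpus(SyntheticConfig(n_themes=3, noise=0.0, seed=5))
records = extract_synthetic(corpus)
clustering, scored, gold = run_synthetic_pipeline(corpus, n_runs=50, base_seed=5)

schema = load_schema()
# map the synthetic gold themes onto chemical-gene schema symbols so the
# table has the real column layout
symbol_map = dict(zip(sorted(gold.theme_symbols()), ["N", "B", "E+"]))
supports = scored.supports.rename(
    columns=lambda c: c.replace(c.split("_", 1)[1], symbol_map.get(c.split("_", 1)[1], c.split("_", 1)[1]))
)
scored_rows = supports[supports[[c for c in supports if c.startswith("support_")]].sum(axis=1) > 0]

with tempfile.TemporaryDirectory() as tmp:
    part1 = Path(tmp) / "part1.tsv"
    part2 = Path(tmp) / "part2.tsv"
    write_part1(scored_rows, schema, "chemical-gene", part1)
    write_part2(records, part2)

    back1 = read_part1(part1, schema, "chemical-gene")
    back2 = read_part2(part2)
    print(f"Part I:  {len(back1)} paths x {len(back1.columns)} columns")
    print(f"Part II: {len(back2)} sentence records")
    pairs = [(r.entity1_formatted, r.entity2_formatted) for r in back2]
    print(f"Part II sorted by entity pair: {pairs == sorted(pairs)}")
    print("\nfirst Part I row:")
    print(back1.iloc[0][back1.iloc[0] > 0].to_string())

# The two files together are the network: Part II rows are the multigraph
# edges (one per sentence-level claim), Part I attaches the theme weights
# to each edge's dependency path.
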