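"""A miniature survey: many samples, grouped summaries, and a p histogram.

Builds three synthetic "datasets" whose communities differ in their true
exponent, writes them as long-format CSVs, reads them back through the
dialect-aware reader, batch-fits every sample, and prints the per-group
summary rows plus the binned frequency distribution of p.
"""

import tempfile
from pathlib import Path

import fractalsad as fs

workdir = Path(tempfile.mkdtemp(prefix="fractalsad_survey_"))
groups = {"meadow": 0.8, "stream": 1.0, "canopy": 1.4}

all_fits = []
for name, p_true in groups.items():
    samples = []
    for seed in range(60):
        sad = fs.generate_multinomial(
            fs.SyntheticSpec(model="multinomial_power_law", p_true=p_true,
                             S=80, N=20_000, seed=seed)
        )
        samples.append(fs.RankAbundance(f"{name}_{seed}", sad.abundances, group=name))
    path = workdir / f"{name}.csv"
    fs.write_abundance_table(samples, path)
    result = fs.read_abundance_table(
        path, fs.AbundanceTableDialect(group_label=name)
    )
    fits = fs.fit_collection(result.samples)
    all_fits.extend(fits.fits)
    print(f"read {len(result)} samples from {path.name}, "
          f"fitted {len(fits)}, excluded {fits.n_excluded}")

print("\ngroup      max    min    median mean   +-SE     n")
for row in fs.summarize_by_group(all_fits, "p"):
    print(f"{row.group:<10} {row.maximum:<6.3f} {row.minimum:<6.3f} "
          f"{row.median:<6.3f} {row.mean:.3f} +-{row.standard_error:.3f} {row.n_samples:>4}")

hist = fs.p_histogram(all_fits)
print("\nfrequency distribution of p (bins of width 1/3):")
for lo, hi, count in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
    bar = "#" * (count // 2)
    print(f"  [{lo:.2f}, {hi:.2f}): {count:>4} {bar}")

print("\nEach group's mean tracks its generating exponent, and the pooled")
print("histogram peaks in the bins around p = 1 - the pattern large real")
print("surveys show when most communities sit near Zipf's law.")
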