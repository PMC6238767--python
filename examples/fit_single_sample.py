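"""Fit the rank-abundance exponent to one small community.

A six-species community with counts proportional to 1, 1/2, ..., 1/6 is the
canonical Zipf case: the estimator returns p = 1 exactly, with R^2 = 1.  A
noisier community gives p away from 1 and R^2 below 1.
"""

import numpy as np

import fractalsad as fs

zipf = fs.RankAbundance("zipf6", np.array([60.0, 30, 20, 15, 12, 10]))
fit = fs.estimate_p(zipf)
print(f"{fit.sample_id}: p = {fit.p:.4f}, R^2 = {fit.r_squared:.4f}, S = {fit.S}")

rough = fs.RankAbundance.from_counts("field_plot", [48, 21, 19, 6, 3, 2, 2, 1])
fit2 = fs.estimate_p(rough)
print(f"{fit2.sample_id}: p = {fit2.p:.4f}, R^2 = {fit2.r_squared:.4f}, S = {fit2.S}")

print()
print("p is the exponent of A_r/A_1 = r^-p (p = 1 is Zipf's law; larger p means")
print("steeper dominance). R^2 is the fit quality on log rank vs log abundance.")
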