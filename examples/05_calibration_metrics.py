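"""Summarize a scan into calibration metrics and QQ data.

Takes p-values from a null scan and reports the genomic inflation
factor (median observed statistic over the null chi-square median),
the empirical type-I error expressed relative to the nominal level,
and thinned QQ points ready for plotting.
"""

import romgei as rg
from romgei.evaluate import summarize
from romgei.nullmodel import NullModelSpec

ped = rg.build_pedigree(300, 50)
km = rg.compute_kinship(ped)
x1, x2 = rg.simulate_exposures(km, seed=3)
trait = rg.simulate_trait(km, x1, x2, rg.calibrate_effects(), seed=4)
fit = rg.fit_null_reml(
    NullModelSpec.from_kinship(trait.y, rg.null_design(x1, x2), km)
)
panel = rg.simulate_genotypes(ped, rg.draw_mafs(5000, seed=5), seed=6)
results = rg.scan(fit, panel, x1[:, None], strategies=("RoM",))

ok = results[results.skip_reason.isna()]
summ = summarize(ok.p_I.to_numpy(), df=1, alpha=0.01,
                 statistics=ok.T_I.to_numpy(), thin=200)
print(f"n_tests        : {summ.n_tests}")
print(f"lambda_GC      : {summ.lambda_gc:.3f}   (1 = perfectly calibrated)")
print(f"t1e ratio at 1%: {summ.t1e_ratio:.2f} +- {summ.t1e_se:.2f} "
      "(rejections / nominal)")
print("last QQ points (expected vs observed -log10 p):")
for e, o in summ.qq[-3:]:
    print(f"  {e:6.3f}  {o:6.3f}")
# On null data the QQ points should hug the diagonal; systematic
# departure of the tail flags inflation (above) or deflation (below).
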