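"""3-D virtual melanin staining scored against phantom ground truth.

Simulates a full z-stack (30 planes, 5 um apart) over the default phantom,
builds the corrected-red stain volume, and reports Dice overlap and ROC AUC
against the voxel-level melanin truth.  Takes a couple of minutes.
"""

from skinmpm.pipeline import melanin_benchmark

result = melanin_benchmark(seed=0)

print(f"z-stack planes        : {result.n_planes}")
print(f"stain threshold       : {result.threshold:.2f} counts (Otsu policy)")
print(f"Dice overlap          : {result.dice:.3f}")
print(f"ROC AUC               : {result.auc:.3f}")
print()
print("per-depth melanin-positive fraction (first 10 planes):")
for k, frac in enumerate(result.per_depth_fraction[:10]):
    print(f"  {5*(k+1):4d} um  {frac*100:5.2f}%")
print()
print("AUC close to 1 means the corrected-red score ranks true melanin "
      "voxels above melanin-free tissue almost everywhere; the Dice value "
      "reflects the single Otsu operating point on that score.")
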