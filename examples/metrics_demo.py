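"""Score a naive intensity-threshold segmentation with the metric suite.

Generates one noisy phantom, segments the whole tumour by thresholding the
FLAIR channel, and reports DSC, Jaccard and the Hausdorff distance against
the exact ground truth — then repeats at higher noise to show all three
metrics degrade together.
"""

import numpy as np

from ecatbrats import PhantomSpec, dsc, generate_phantom, hausdorff, iou

for sigma in (0.05, 0.3, 0.8):
    case = generate_phantom(PhantomSpec(noise_sigma=sigma, seed=1))
    flair = case.volume.intensities[3]
    wt_pred = (flair > 1.4).astype(np.uint8)   # background 1.0 + half the WT contrast
    wt_true = case.mask.channels[0]
    hd, flagged = hausdorff(wt_true, wt_pred, spacing=case.volume.spacing)
    print(f"noise sigma {sigma:.2f}:  DSC {dsc(wt_true, wt_pred):.3f}  "
          f"IoU {iou(wt_true, wt_pred):.3f}  HD {hd:.2f} mm"
          + ("  [empty-region flag]" if flagged else ""))

print("\nhigher noise -> lower overlap, larger boundary distance; "
      "IoU always equals DSC/(2-DSC).")
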