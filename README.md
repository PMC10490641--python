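# chebseg

Liver and liver-tumor segmentation of CT slices with a superpixel
region-graph and a Chebyshev spectral graph-convolutional network.

Segmenting the liver — and the tumors inside it — in abdominal CT is hard
because neighboring organs (heart, spleen, stomach, kidneys) have nearly the
same intensity and texture. `chebseg` approaches the problem as *node
classification on a region graph*: instead of labelling half a million
pixels, a slice is first clustered into a few hundred SLIC superpixels, and
a small graph neural network decides, per superpixel, whether it is liver
(or, after fine-tuning, tumor). It is aimed at medical-image-analysis
researchers who want a compact, fully inspectable, CPU-friendly graph
formulation of semantic segmentation — every stage, including the network's
forward and backward passes, is plain numpy.

## Method

1. **Preprocessing.** Raw Hounsfield intensities are windowed to the
   soft-tissue range: pixels outside [0, 150] HU are set to 0, then divided
   by the window width so intensities lie in [0, 1].
2. **Graph embedding.** SLIC oversegments the slice into C superpixels
   (default 600 for real 350×350 CT; configurable). Region *i* becomes a
   node with feature f_i = mean intensity. Regions sharing a 4-connected
   border are joined by an edge weighted

       w_ij = exp(−β (f_i − f_j)²),   β = 10 by default.

3. **Spectral filtering.** With W the weighted adjacency, D the degree
   matrix and L = D − W the combinatorial Laplacian, signals are filtered by
   K-order Chebyshev polynomials of the rescaled operator
   L̃ = 2L/λ_max − I:

       y = Σ_{k=0}^{K−1} θ_k T_k(L̃) x,

   evaluated via the recurrence T_k x = 2 L̃ T_{k−1} x − T_{k−2} x, which is
   exactly equivalent to filtering in the graph Fourier basis but never
   eigendecomposes in the training path.
4. **Network.** An affine lift 1→16 channels, four Chebyshev convolution
   layers (16, 16, 16, 2 channels; orders K1..K4, default 3) each with batch
   normalization and (for the first three) ReLU, dropout 0.2, a per-node
   dense map and softmax. Training minimizes an area-weighted soft-Dice
   loss with Adam (lr 0.001, weight decay 5·10⁻⁴), one graph per step,
   with 10-fold cross-validation. Tumor segmentation fine-tunes the
   liver-trained weights on tumor node labels.
5. **Evaluation.** Pixel-level Dice, IoU, accuracy, sensitivity/recall and
   precision; ROC over node scores; robustness under additive white
   Gaussian noise across a grid of signal-to-noise ratios.

A packaged phantom generator produces pseudo-HU slices with an elliptical
liver, an inset darker tumor, confounding organ ellipses of liver-like
intensity and pixel noise — with analytic ground truth — so the entire
pipeline runs and is tested without any external dataset. Real data in
LiTS17-style NIfTI format (labels 0/1/2 = background/liver/tumor) is read
through the same interface.

## Worked example

`examples/04_train_liver.py` trains on 30 phantoms (96×96, 300 superpixels,
40 epochs) with 5-fold cross-validation and prints:

```
cross-validation mean:
  accuracy     0.982
  dsc          0.910
  iou          0.896
  sensitivity  0.897
  recall       0.897
  precision    0.999
holdout:
  accuracy     1.000
  dsc          0.999
  iou          0.999
  sensitivity  0.999
  recall       0.999
  precision    1.000
final training Dice loss: 0.0608
```

The cross-validation rows are averaged over folds trained on ~19 slices
each; the holdout row is the final model (trained on all 24 training
slices) evaluated on 6 unseen slices. Dice ≈ 1 means the classifier
recovers the liver despite confounder organs of nearly identical mean
intensity — it must use the graph neighborhood, not just the node feature.
`examples/05_tumor_and_noise.py` continues with tumor fine-tuning (Dice
0.199 before → 0.989 after) and a noise sweep in which liver pixel accuracy
falls from 1.000 at +40 dB to 0.747 at −10 dB.

The other examples demonstrate phantom generation/NIfTI export, region-graph
construction, and the equivalence of recurrence-based Chebyshev filtering
with exact spectral filtering (error ~1e−15).

A thin CLI wraps the same pipeline:

```bash
chebseg generate data/ --n-cases 20 --seed 7
chebseg train --seed 7 --epochs 60 --out runs/liver
chebseg finetune-tumor runs/liver/liver_model --seed 7 --out runs/tumor
chebseg noise-sweep runs/liver/liver_model --snrs "40,20,0,-10"
chebseg region-study --regions "200,600,1000"
```

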