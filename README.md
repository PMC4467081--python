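# cellseg

Automated segmentation of cells in **negative phase contrast** microscopy
images: every cell in the field of view is located, its boundary is traced
with a thresholding-seeded expanding active contour, and touching cells are
counted and split using the peaks of their light intensity.

## Who this is for

Labs doing label-free, long-term imaging of adherent cells (migration,
wound healing, morphology screens) who need per-cell outlines and areas
from plain phase contrast frames — no fluorescent reporters, no manual
contour initialization. In negative phase contrast, cell bodies are
consistently *brighter* than the background (taller cells brighter still),
which this package exploits end to end.

## The method

A transparent cell of thickness *h* in medium of refractive index *n₁*
(cell index *n₂* > *n₁*) shifts the phase of the illumination by

    Δφ = 2π (n₂ − n₁) h / λ,

and for small Δφ the recorded intensity is approximately linear in it,
I ≈ 1 + 2Δφ. A cell therefore images as a convex intensity hill with a
single apex above its nucleus. The pipeline turns that into a segmentation
in three moves:

1. **Global thresholding** (image mean + offset, Otsu + offset, or an
   absolute value) gives preliminary masks, which sit *inside* the true
   boundaries.
2. **Contour expansion.** Each mask boundary seeds a closed parametric
   snake **v**(s) minimizing E = ∮ (½α|**v**_s|² + ½β|**v**_ss|² + E_ext) ds,
   whose Euler–Lagrange equation α**v**_ss − β**v**_ssss − ∇E_ext = 0 is
   integrated semi-implicitly (periodic pentadiagonal system, solved as a
   circulant by FFT). The image force −κ∇I pushes the curve down the
   intensity slope — outward — until it rests on the cell edge; iteration
   stops when the mean intensity along the curve changes by < 0.002 for 10
   consecutive steps.
3. **Clump splitting.** A mask holding several touching cells shows one
   regional intensity maximum per cell (after Gaussian smoothing removes
   organelle "pseudo-peaks"). Pixels are assigned to their nearest peak,
   and each sub-area boundary seeds its own expansion, which corrects the
   straight nearest-peak division.

Watershed on the negated distance transform and a two-phase region-based
active contour are included as baselines, a physics-grounded phantom
generator provides ground-truthed synthetic scenes, and an evaluation
module scores over-segmentation, under-segmentation and false detections.

## Worked example

```python
from cellseg import synthetic, pipeline, evaluate

spec = synthetic.clump_scene(k=4, seed=0)       # four touching cells
image, truth = synthetic.generate_scene(spec)
result = pipeline.segment(image)

print(f"cells found: {result.n_cells}")
for c in result.cells:
    print(f"  cell {c.cell_id}: {c.area_um2:6.1f} um^2  "
          f"peak at row {c.peak_rc[0]:5.1f}, col {c.peak_rc[1]:5.1f}  "
          f"from clump: {c.from_clump}")
ious = evaluate.per_cell_iou(result.label_map, truth.label_map)
print("per-cell IoU vs truth:", [round(float(v), 3) for v in ious])
```

prints

```
cells found: 4
  cell 1:  593.4 um^2  peak at row  41.0, col  84.0  from clump: True
  cell 2:  625.2 um^2  peak at row  63.0, col 110.0  from clump: True
  cell 3:  454.8 um^2  peak at row  96.0, col  96.0  from clump: True
  cell 4:  545.0 um^2  peak at row  97.0, col 131.0  from clump: True
per-cell IoU vs truth: [0.861, 0.945, 0.925, 0.932]
```

— four cells recovered from one connected mask, each with its area in µm²
(pixel pitch defaults to the 900 µm × 686 µm field of view at 1344 × 1024
px, ≈ 0.67 µm/px) and ~0.9 overlap with the generator's ground truth.

The same machinery is scriptable from the shell:

```bash
cellseg synth --preset field130 --seed 3 --out scene/
cellseg segment scene/image.tif --out seg/
cellseg eval --pred seg/labels.tif --truth scene/truth.tif
cellseg baseline watershed scene/image.tif --out ws/
```

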