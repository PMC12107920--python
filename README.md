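# histolink

Connecting AI decision support to the pathology laboratory information
system over HL7 v2 messaging.

Deep-learning models for whole-slide images (WSIs) rarely reach routine
diagnostics because nothing connects them to the software pathologists
actually work in: the anatomic-pathology laboratory information system
(AP-LIS). `histolink` implements an open integration pattern in which
the AP-LIS and an external AI decision-support service (AI-DSS) talk
HL7 v2.6 over MLLP/TCP:

1. the AP-LIS sends a laboratory order (`OML^O33`) naming a model
   (`SPM.4.1^SPM.4.2`) and a slide's filesystem path (`OBR.13`) — either
   automatically when a slide is digitized (*default mode*, driven by a
   tissue/stain correspondence table) or on a pathologist's request
   (*on-demand mode*);
2. the service acknowledges (`ACK`) before any processing, queues the
   request FIFO, and a single sequential worker runs inference —
   tissue segmentation, tile grid, per-tile scores or attention, and a
   slide-level call where the model provides one;
3. results go back as an `OUL^R21`: the first OBX segment is always the
   model name; patch-level models add the tissue mask (JPEG), the
   tile-prediction CSV and run metadata (JSON) as Base64 OBX segments
   (binary models also the five top-scoring tile crops); slide-level
   models add the predicted label / risk class and its score;
4. a reviewable heatmap overlay is exported for the viewer as GeoJSON:
   **measurement maps** (per-tile target-class score), **color maps**
   (per-tile argmax class), or **density maps** (1–9 points per tile,
   `min(9, max(1, floor(10·p)))` for percentile-ranked attention `p`).

Any stage failure (including delivery failures and a negative LIS
acknowledgment) counts as a failed attempt; a request is tried at most
three times, then the next queued slide proceeds.

The shipped registry reproduces a 16-model catalogue (8 built-in
patch-level classifiers, 2 custom patch-level, 3 built-in MIL
slide-level models, 2 attention-MIL biomarker models, 1 custom MIL
tissue classifier). Model backends are pluggable; the shipped backend
is synthetic — a pure function of (seed, slide, model) that reproduces
the real toolboxes' output contracts exactly, so the whole loop runs at
desk scale with no weights or downloads.

## Worked example

```python
from histolink.fixtures import SyntheticSlideSpec, make_slide
from histolink.registry import load_registry
from histolink.pipeline import run_inference
from histolink.heatmap import build_project, summarize_slide

reader = make_slide(SyntheticSlideSpec(seed=7, dimensions=(1024, 1024),
                                       n_blobs=5, blob_size=(300, 600)), "demo")
registry = load_registry()

spec = registry.resolve("breast-tumor-resnet34.tcga-brca")
bundle = run_inference(reader, spec, seed=7)
print("tiles:", len(bundle.patch_table))
print(bundle.patch_table.head(3).to_string(index=False))

spec = registry.resolve("braf-attMIL-marugoto")
bundle = run_inference(reader, spec, seed=7)
print(summarize_slide(spec, bundle.slide_label, bundle.slide_score))
```

prints

```
tiles: 10
  x   y  height  width  no-tumor    tumor
350 350     175    175  0.365671 0.634329
525 350     175    175  0.168203 0.831797
175 525     175    175  0.255680 0.744320
model: braf-attMIL-marugoto; prediction: MUT; score: 0.67
```

The tile table is the patch-level CSV contract: tile origin and size in
base pixels, then one probability column per model class; the breast
model found 10 tissue tiles and scored each for `tumor` (these scores
feed the measurement map). The second model is an attention-MIL
biomarker classifier: its slide-level call (`MUT`, score 0.67) is the
one-line summary the LIS shows as slide description, and its per-tile
attention becomes a density map.

The same loop over the wire, from a shell:

```sh
histolink fixtures run-loop --slides 1 \
    --model breast-tumor-resnet34.tcga-brca --seed 5 --workdir loop
```

which sends the order through a mock LIS, processes it through the
queued runtime, and reports `"obx_counts": [9]` — the binary patch-level
layout (1 model name + 3 artifacts + 5 top tiles). A long-running
service is `histolink serve`; `histolink send-order` submits single
orders; `histolink registry validate` checks a site's model catalogue.

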