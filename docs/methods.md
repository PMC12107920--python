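# Methods

## The integration model

`histolink` models the interconnection of two systems: the
anatomic-pathology laboratory information system (AP-LIS), which owns
cases, slides and reports, and an AI decision-support service (AI-DSS)
hosting deep-learning models. All communication is HL7 v2.6
pipe-and-hat over MLLP (`0x0B … 0x1C 0x0D`) on TCP, UTF-8 on the wire,
with the standard encoding characters `| ^ ~ \ &` and escape sequences
applied to user strings.

Three message types form the profile:

* **`OML^O33`** — one order = one slide × one model. Segment order is
  MSH, PID, SPM, ORC, OBR; the profile requires exactly one SPM and one
  ORC/OBR pair. The model code/name travel in `SPM.4.1^SPM.4.2`, the
  WSI location in `OBR.13`. The location follows scanner conventions: a
  plain file for `.svs`/`.tif`, a directory containing `Slidedat.ini`
  for `.mrxs` containers.
* **`ACK`** — sent on receipt, before any processing: `AA` accepted and
  enqueued, `AE` unparseable input, `AR` profile violation.
  Acknowledging an `ACK` is rejected.
* **`OUL^R21`** — results as OBX segments with strictly sequential set
  ids from 1. OBX#1 is always the model name (ST). Patch-level models
  append three ED segments — tissue-mask JPEG, tile-prediction CSV,
  run-metadata JSON — Base64-encoded (RFC 4648, no line wrapping);
  binary patch-level models additionally the top-5 tile JPEGs.
  Slide-level models append an ST label (predicted class or risk class)
  and an NM score, for totals of 9, 4, and 3 OBX segments for the
  binary-patch, multiclass-patch and slide-level layouts respectively.

Profile decisions the wire standard leaves open: OBX value types are ED
for binary payloads, ST for text, NM for scores; the order mode travels
in `OBR.11` (`A` automatic/default, `O` on-demand); message control ids
are a per-process monotone counter with a configurable prefix, and both
control ids and MSH-7 timestamps are injectable so tests can compare
transcripts byte-for-byte.

## Queueing and retry

Orders are acknowledged immediately and processed strictly FIFO by a
single sequential worker (listening continues concurrently); this makes
completion order of successful requests equal arrival order by
construction. Any failure between model resolution and receipt of the
LIS acknowledgment — including an `AE`/`AR` acknowledgment and ACK
timeout (default 30 s, configurable) — counts as one failed attempt.
Failed requests re-enter at the queue head and retry immediately (no
backoff); after the third failed attempt the request is marked failed
and the queue moves on, so a permanently failing slide cannot block
later ones. The queue is in-memory; persistence across restarts is out
of scope. Two counters are recorded per request: total time from order
arrival to the final acknowledgment, and inference-plus-project time.

## Model registry

One YAML file holds the model catalogue and the tissue/stain
correspondence table that drives default mode. Each entry carries the
task kind (`patch_binary`, `patch_multiclass`, `slide_mil_class`,
`slide_mil_survival`), ordered output classes, the visualization style,
patching geometry, and a `default_eligible` flag. Predictive and
prognostic (biomarker/survival) models ship as on-demand only, but the
flag is per model rather than hard-coded by task kind, so a site can
change the policy by editing the config. Correspondence lookups are
case-insensitive on tissue and stain, ordered, and deduplicated; rows
referencing unknown models are rejected at load time.

The shipped catalogue lists 16 models. The attention-MIL path uses
patches of 224 px at 1.14 microns per pixel (mpp); patch-level entries
carry the per-model geometry their deployment config would supply
(these values are illustrative for the emulated backends). The
correspondence table is likewise illustrative and site-configurable.

## Inference backends

Backends reproduce the *output contracts* of the three deployment
toolboxes, not their networks:

* **Tissue segmentation and patching** — Otsu threshold on the grayscale
  thumbnail (tissue darker than glass; pixels above gray level 220 are
  always background), small-object removal, then a regular
  non-overlapping grid of square tiles whose edge in base pixels is
  `round(patch_size_px × spacing_mpp / slide_mpp)`. A tile is kept when
  ≥ 25% of it overlaps the mask. A blank slide yields a valid empty
  grid.
* **Patch-level scoring** — one row per tile: `x, y, height, width` in
  base pixels plus one probability column per class (rows normalized to
  sum 1; a single-class model keeps its raw score). The synthetic
  backend draws each score as a pure hash of (seed, slide basename and
  dimensions, model name, tile coordinates), so identical seeds give
  identical tables regardless of directory prefixes.
* **MIL scoring** — per-tile attention plus its percentile rank
  (fractional average rank via `pandas.Series.rank(pct=True)`: ties
  share the mean of their positions; the maximum is always 1.0). The
  MIL-builtin path emits six columns, the attention-MIL path seven
  (min–max-normalized attention inserted before the percentile). The
  slide table has one row per class (name, probability), or one logit
  per time bin for survival models.
* **Top-k gallery** — for binary patch models, the five tiles with the
  highest target-class score are cropped at native resolution and
  JPEG-encoded, ordered by (score desc, y asc, x asc); fewer when the
  grid is smaller.
* **Risk split** — survival logits map to a risk score via a pluggable
  formula; the class is `high` iff the score is strictly greater than
  the configured median threshold (a score exactly at the median is
  low). Two formulas ship, both explicit stand-ins because the
  published per-model formulas and medians are hosted with the original
  models and not reproduced here: `logit_sum` (default; zero at zero
  input, strictly monotone in every hazard-increasing logit) and
  `neg_cumulative_survival` (discrete-hazard negative sum of the
  survival curve).

CSV artifacts are comma-separated with a header row and `.` decimals;
reads use round-trip float parsing so write → read → write is
bit-identical.

## Heatmap overlays

Tile coordinates are produced in the scanner frame; formats with a
non-zero imaged-region origin (the bounds offset) have it subtracted
before display — a pure translation, with negative results rejected as
data errors.

* *Measurement maps* (binary patch models): one polygon per tile,
  classed as the clinically chosen target class, carrying that tile's
  target-class score verbatim (no renormalization).
* *Color maps* (multiclass patch models): the project declares one
  class per model category with a distinct color from a fixed palette
  keyed by class index; each tile takes the argmax class (ties go to
  the first class in the model's order) and the winning score.
* *Density maps* (MIL models): each tile contributes a polygon carrying
  both the raw and the percentile attention (the standard leaves the
  choice open, so both are emitted) plus
  `min(9, max(1, floor(10·p)))` point detections. The bin boundaries
  are closed on the lower edge with the top bin at p ≥ 0.9; this
  closed form reproduces the stated endpoints (9 points at p ≥ 0.9
  down to 1 point below 0.2). Points fill a deterministic 3×3 sub-grid
  at quarter-tile spacing, centre slot first, so a single point sits
  exactly at the tile centre. The slide-level call is formatted as
  `model: <name>; prediction: <label>; score: <two decimals>` and
  stored as the project description.

Projects export as a directory with a GeoJSON `FeatureCollection`
(detection objects with `classification` name + packed 24-bit RGB
color and a named measurement list) and a JSON manifest; import
reverses the export losslessly. GeoJSON was chosen over the viewer's
binary project format because the latter is tool-version-specific,
while GeoJSON import is a stable viewer feature.

## Synthetic fixtures

Synthetic slides are small tiled TIFFs (elliptical "tissue" blobs on a
bright noisy background) with a JSON sidecar carrying mpp, bounds
offset, tissue type and stain; generation is byte-deterministic in the
spec. Defaults: 2048² region, 0.5 mpp, 3 blobs of 200–500 px span,
H&E. The end-to-end loop driver uses 1024² slides with 5 blobs of
300–600 px so that every shipped patching geometry (tile edges up to
~511 base pixels) finds a non-empty grid — emulating that routine
sections fill much of the scanned region. What the fixtures do *not*
emulate: pyramidal resolution levels, scanner vendor file internals
(beyond the `.mrxs` path-resolution convention), stain variation, and
real model behaviour — passing tests demonstrate the integration
contracts (messaging, queueing, schemas, overlays), not diagnostic
performance on real tissue.

A scripted backend replays a per-attempt plan (succeed / raise /
delay) for exercising the retry path, and a mock LIS peer plays the
other side of the wire: it sends orders, receives results, and
acknowledges per scenario (`AA`, `AE`, or silent to force a timeout),
recording the full transcript.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 512–2048 px
slides, grids of 1–100 tiles, 1,000-order conformance and 1,000-vector
ranking checks, and a 3-slide × 2-model socket loop. Percentile ranks
are compared to an O(n²) brute-force oracle at 1e-12 relative
tolerance; probabilities are exact row-normalized hashes in [0, 1].
Degenerate inputs are defined behaviour: blank slides give empty grids
and valid empty tables, empty prediction tables give valid empty
projects, a MIL model on an empty grid is a contract error (a failed,
retryable attempt), and percentile ranking of an empty list is an
error.

## Known limitations

No authentication or TLS on the transport; no queue persistence; no
real-WSI adapter in this distribution (the slide interface accepts one
readily); the shipped risk formulas and correspondence table are
documented stand-ins; HL7 v3/FHIR and the viewer's binary project
format are out of scope.
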