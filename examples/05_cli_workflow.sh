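#!/usr/bin/env bash
# Shell workflow: simulate -> run -> evaluate -> sweep-k, all via the
# `vae-detect` CLI over NPZ/CSV files.
set -euo pipefail
workdir=$(mktemp -d)

cat > "$workdir/scene.yaml" <<'YAML'
params:
  duration_s: 90.0
  width: 280
  height: 200
  seed: 8
bubbles:
  - {start_frame: 1500, end_frame: 2200, grade: 3}
YAML

vae-detect simulate --config "$workdir/scene.yaml" \
  --out "$workdir/video.npz" --annotations "$workdir/gt.csv"

vae-detect run --video "$workdir/video.npz" --annotations "$workdir/gt.csv" \
  --out "$workdir/scores.csv"

vae-detect evaluate --scores "$workdir/scores.csv" --annotations "$workdir/gt.csv" \
  --min-grade 1 --report "$workdir/report.json"

vae-detect sweep-k --video "$workdir/video.npz" --annotations "$workdir/gt.csv" \
  --values 2,3,4

cat "$workdir/report.json"
rm -rf "$workdir"
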