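#!/usr/bin/env bash
# Shell workflow: synthesize a scene, track it, evaluate against truth.
set -euo pipefail

out=${1:-/tmp/larvatrack_demo}

larvatrack synth --scenario forward_crawl --seed 0 --frames 60 --out "$out/scene"
larvatrack track --input "$out/scene/frames" --out "$out/tracked" \
    --gray-threshold 72 --area-min 160 --area-max 512
larvatrack eval --tracked "$out/tracked/features.csv" \
    --truth "$out/scene/ground_truth.csv" --report "$out/report.csv"

echo "results in $out (features.csv, features_wide.csv, trajectories.png, report.csv)"
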