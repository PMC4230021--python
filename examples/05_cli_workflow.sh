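#!/usr/bin/env bash
# Staged command-line workflow: simulate a dataset, then run the three
# analysis stages with inspectable intermediate files.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

betameth simulate --preset paper-main --seed 7 \
    --n-sites 1500 --n-regions 5 -o "$workdir/sim"

betameth regression "$workdir/sim.counts" "$workdir/sim.design" \
    --factor case -o "$workdir/sites.tsv"

betameth adjust "$workdir/sites.tsv" --window-bp 200 -o "$workdir/adjusted.tsv"

betameth merge "$workdir/adjusted.tsv" --fdr 0.01 --min-cpgs 10 \
    -o "$workdir/dmrs.bed"

echo "== first DM regions =="
head -n 3 "$workdir/dmrs.bed"
echo "== true regions =="
head -n 3 "$workdir/sim.truth.bed"
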