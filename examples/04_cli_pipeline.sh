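#!/usr/bin/env bash
# Full pipeline from the shell: simulate a ground-truth scenario into a
# directory, then run all six stages from the generated YAML config and
# inspect the report tables.
set -euo pipefail

workdir=$(mktemp -d)

protmr simulate --seed 7 --panel-size 50 --out "$workdir/scenario"
protmr run --config "$workdir/scenario/config.yaml" --out "$workdir/report"

echo
echo "--- mediation table ---"
cat "$workdir/report/mediation.tsv"
echo
echo "--- colocalization ---"
cat "$workdir/report/coloc.tsv"

# the mediation row reports the exposure->outcome, exposure->protein and
# protein->outcome path estimates, their product (the indirect effect)
# and the mediated proportion with its delta-method CI
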