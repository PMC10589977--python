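#!/bin/sh
# The same workflow as example 03, driven entirely from the shell.
# Produces a synthetic fixture, analyzes it into a store, verifies the
# stored values by replay, and exports the normalized table as CSV.
set -e
work=$(mktemp -d)

gelquant synth "$work/fx" --seed 17
gelquant --store "$work/gel.db" init
gelquant --store "$work/gel.db" project "Lab/Blots"
gelquant --store "$work/gel.db" gel "demo" --project "Lab/Blots"
gelquant --store "$work/gel.db" lanes 1 "$work/fx/lanes.json"
gelquant --store "$work/gel.db" image 1 "$work/fx/image.tif"
gelquant --store "$work/gel.db" analyze 1 "$work/fx/analysis.json"
gelquant --store "$work/gel.db" replay 1
gelquant --store "$work/gel.db" export "$work/results.csv"

echo "--- normalized values (w ~ 1: equal signal per ug loaded) ---"
cat "$work/results_normalized.csv"
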