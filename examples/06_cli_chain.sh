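#!/bin/sh
# The same workflow from the shell; stages compose via directories with
# PNG images plus a path,label,patient_id manifest.
set -e
work=$(mktemp -d)

shortcutscope synth   --out "$work/pool"    --n 400 --seed 1
shortcutscope build   --pool "$work/pool"   --out "$work/trainset" --kind S --seed 2
shortcutscope train   --data "$work/trainset" --out "$work/run" --ensemble-size 3 --seed 3
shortcutscope synth   --out "$work/cohort"  --n-pos 150 --n-neg 150 --seed 4
shortcutscope certify --run "$work/run" --exam "$work/cohort" \
                      --out "$work/cert.json" --seed 5
# exit 0 = certified; deploy it:
shortcutscope detect  --run "$work/run" --data "$work/cohort" \
                      --certification "$work/cert.json" \
                      --out "$work/detect.json" --seed 6
# exit 0 = no shortcut flagged, 2 = shortcut flagged
echo "reports in $work"
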