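#!/usr/bin/env bash
# One-time download of the deposited coordinate files used by the
# reproduction analyses and the deposited-entry acceptance tests.
# Files land in data/structures/ as mmCIF; the analysis tool itself never
# touches the network.
set -euo pipefail

dest="$(dirname "$0")/../data/structures"
mkdir -p "$dest"

for code in 8q5u 6e58 8a49 6mds 3ave; do
    out="$dest/${code}.cif"
    if [[ -s "$out" ]]; then
        echo "already present: $out"
        continue
    fi
    echo "fetching $code ..."
    curl -fsSL "https://files.rcsb.org/download/${code^^}.cif" -o "$out"
done
echo "done; files in $dest"
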