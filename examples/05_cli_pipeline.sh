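#!/usr/bin/env bash
# The same workflow from the command line, stage by stage and end-to-end.
set -euo pipefail
workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

cat > "$workdir/cfg.toml" <<'EOF'
[cohort]
n_per_group = 3
t_frames = 96
voxels_per_roi = 6
EOF

# One-shot: simulate + preprocess + connectivity + graph metrics + stats.
visconn run-all --config "$workdir/cfg.toml" --outdir "$workdir/run" --seed 5

# Figures from a finished results directory.
visconn report --results "$workdir/run"

echo "outputs:"
find "$workdir/run" -maxdepth 1 | sort
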