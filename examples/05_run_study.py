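"""Run the end-to-end synthetic study pipeline on a small cohort.

Simulates three subjects in the control condition, fits all model variants
to each, compares variants by summed BIC, computes behavioral metrics, and
writes every table plus a manifest of content hashes under ``study_out/``.
Rerunning the same configuration reproduces all files byte-for-byte.
"""
from pathlib import Path

from reachrl import RunConfig, run_study

config = RunConfig(
    seeds=(1, 2, 3),
    condition="control",
    particles=500,
    optimizer_maxfev=80,
    outdir=Path("study_out"),
)
manifest = run_study(config)

print(f"wrote {len(manifest['files'])} files:")
for rel in manifest["files"]:
    print(f"  study_out/{rel}")
print(f"config hash: {manifest['config_sha256'][:16]}...")

# study_out/bic.csv holds the summed-BIC grid (delta 0 marks the winning
# variant); fits.csv one row per subject x variant; metrics.csv the
# behavioral summaries; manifest.json a hash of every output for
# reproducibility checks.
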