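"""Run the whole pipeline end to end from a config and inspect the manifest.

Equivalent to `diallel all --config cfg.yaml` on the command line.
"""

import json
import tempfile
from pathlib import Path

from diallel import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(
        out_dir=str(Path(tmp) / "run"),
        seed=1,
        n_founders=8,
        n_sites=150,
        n_conditions=2,
        n_causal=8,
        n_perm=20,
        alpha=0.1,
    )
    manifest = run_pipeline(config)
    print("stage outputs written:")
    for name, checksum in manifest["outputs"].items():
        print(f"  {name:24s} sha256 {checksum[:12]}…")
    print("\nsite filter report:", manifest["filter_report"])
    print("heritability table:")
    print(Path(config.out_dir, "heritability.tsv").read_text())
    print("MAF enrichment:", json.dumps(manifest.get("maf_enrichment", {}), indent=2, default=str)[:400])
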