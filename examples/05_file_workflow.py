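"""File-based workflow: export a workspace, load it, run the pipeline.

The same analyses are available from the shell once a workspace exists:

    periscreen run --config ws/config.yaml
    periscreen psa --config ws/config.yaml --n 1000 --seed 7
"""

import tempfile
from pathlib import Path

import periscreen as ps

ws = Path(tempfile.mkdtemp()) / "ws"
config_path = ps.export_reference_workspace(ws)
print("workspace files:", sorted(p.name for p in ws.iterdir()))

cfg = ps.load_run_config(config_path)
status = ps.run_pipeline(cfg)
print("pipeline exit status:", status)
print("outputs:", sorted(p.name for p in cfg.output_dir.iterdir()))
print()
print((cfg.output_dir / "cua_table.csv").read_text())
print((cfg.output_dir / "run.log").read_text())
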