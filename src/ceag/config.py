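"""Run configuration and manifests: every run is replayable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    A manifest echoing the resolved configuration is written next to
    every output set so results can be replayed exactly.
    """

    seed: int = 20260
    ordering: str = "STRIPES_BY_DOC"
    grid_width: int = 12
    mask: str = "content_trust"
    confidence: float = 0.95
    out_dir: str = "ceag_out"
    gold_path: Optional[str] = None
    input_paths: Tuple[str, ...] = ()
    log_level: str = "INFO"

    def manifest(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True).encode()
        d["config_sha256"] = hashlib.sha256(blob).hexdigest()
        return d

    def write_manifest(self, path) -> None:
        pathlib.Path(path).write_text(
            json.dumps(self.manifest(), indent=2) + "\n", encoding="utf-8"
        )
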