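"""Machine-readable run manifest written next to every CLI output.

The manifest records the resolved configuration (after applying the
precedence CLI flags > config file > defaults), the typing coverage of
the run — users are advised to check the multipolar percentage before
trusting TAAM results — and the provenance of the scattering model
(mode, radiation, Gaussian dialect).  ``RunManifest.json_schema_text``
is checked in as ``data/run_manifest.schema.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

SCHEMA_PATH = Path(__file__).parent / "data" / "run_manifest.schema.json"


class CoverageInfo(BaseModel):
    n_atoms: int = Field(ge=0)
    multipolar: int = Field(ge=0)
    spherical_slater: int = Field(ge=0)
    gaussian_iam: int = Field(ge=0)
    multipolar_coverage: float = Field(ge=0.0, le=1.0)


class RunManifest(BaseModel):
    command: str
    model_path: str | None = None
    bank_path: str | None = None
    mode: str | None = None
    radiation: str | None = None
    table_dialect: str | None = None
    d_min: float | None = Field(default=None, gt=0)
    seed: int | None = None
    outputs: list[str] = []
    coverage: CoverageInfo | None = None
    extra: dict = {}

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def json_schema_text(cls) -> str:
        return json.dumps(cls.model_json_schema(), indent=2, sort_keys=True) + "\n"


def coverage_info(report: dict) -> CoverageInfo:
    return CoverageInfo(
        n_atoms=report["n_atoms"],
        multipolar=report["counts"]["multipolar"],
        spherical_slater=report["counts"]["spherical-slater"],
        gaussian_iam=report["counts"]["gaussian-iam"],
        multipolar_coverage=report["multipolar_coverage"],
    )
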