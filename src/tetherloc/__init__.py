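"""tetherloc: cross-link guided localization of tethered protein domains,
conformer-state discrimination and rigid-body fitting into EM density."""

from importlib import resources as _resources

from .structio import (
    RigidTransform,
    StructureModel,
    ca_distance,
    read_structure,
    superpose,
    write_structure,
)

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled reference data file."""
    return _resources.files("tetherloc") / "data" / name
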