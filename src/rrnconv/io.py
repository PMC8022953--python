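"""On-disk formats: region maps, aligned FASTA families, event tables.

A *region map* is a small YAML config naming the operon copies and, per
region, an id, a kind (``gene`` or ``spacer``) and the aligned
multi-FASTA file holding the seven copies::

    operons: [rrnA, rrnB, rrnC, rrnD, rrnE, rrnG, rrnH]
    regions:
      - {id: 16S, kind: gene, file: 16S.fasta}
      - {id: 23S, kind: gene, file: 23S.fasta}
      - {id: spacer, kind: spacer, file: spacer.fasta}

Events travel as TSV with one row per conversion: lineage, region,
recipient, comma-joined changed positions, comma-joined donor
candidates, and the min/max extent bounds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .alignment import OperonAlignment, decode_row, load_region_alignment
from .inference import EventSet, GeneConversionEvent, events_from_frame, events_to_frame

__all__ = [
    "load_region_map",
    "load_family",
    "write_family",
    "write_events_tsv",
    "read_events_tsv",
]


def load_region_map(path: str | Path) -> dict:
    """Parse and validate a region-map YAML file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "operons" not in cfg or "regions" not in cfg:
        raise ValueError(f"region map {path} must define 'operons' and 'regions'")
    for reg in cfg["regions"]:
        if not {"id", "kind", "file"} <= set(reg):
            raise ValueError("every region needs 'id', 'kind' and 'file'")
        if reg["kind"] not in ("gene", "spacer"):
            raise ValueError(f"unknown region kind {reg['kind']!r}")
    cfg["_base_dir"] = path.parent
    return cfg


def load_family(
    region_map: dict | str | Path, base_dir: str | Path | None = None
) -> dict[str, OperonAlignment]:
    """Load every region alignment referenced by a region map."""
    if not isinstance(region_map, dict):
        region_map = load_region_map(region_map)
    base = Path(base_dir) if base_dir is not None else Path(region_map.get("_base_dir", "."))
    out = {}
    for reg in region_map["regions"]:
        out[reg["id"]] = load_region_alignment(
            base / reg["file"], reg["id"], region_map["operons"], kind=reg["kind"]
        )
    return out


def write_family(
    alignments: Mapping[str, OperonAlignment], out_dir: str | Path
) -> Path:
    """Write one aligned FASTA per region plus a region map; returns the map path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    regions = []
    operons = None
    for region_id, aln in alignments.items():
        operons = list(aln.operon_ids)
        fname = f"{region_id}.fasta"
        with open(out_dir / fname, "w") as fh:
            for op, seq in aln.sequences().items():
                fh.write(f">{op}\n{seq}\n")
        regions.append({"id": region_id, "kind": aln.kind, "file": fname})
    map_path = out_dir / "region_map.yaml"
    with open(map_path, "w") as fh:
        yaml.safe_dump({"operons": operons, "regions": regions}, fh, sort_keys=False)
    return map_path


def write_events_tsv(events: EventSet | Sequence[GeneConversionEvent], path: str | Path) -> None:
    events_to_frame(list(events)).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> EventSet:
    df = pd.read_csv(path, sep="\t", dtype={"lineage": str})
    out = EventSet()
    out.extend(events_from_frame(df))
    return out
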