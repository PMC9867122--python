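"""Plain-text readers and writers for the pipeline's file formats.

Formats (all text, versionable and diff-able):

* compounds: TSV with columns compound_id, name, status, n_bits,
  fingerprint_hex (fingerprint packed big-bit-first and hex-encoded);
* site models: JSON with per-protein sites, each carrying a confidence
  score and hex-encoded predicted-ligand fingerprints;
* indication catalog: two-column TSV (indication_id, compound_id);
* interaction matrix: TSV, first row protein ids, first column compound
  ids, scores with 6 decimal places;
* panels: one protein id per line;
* dose-response / Ct tables: CSV with the documented column schemas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from drugsig.datatypes import (
    BindingSite,
    CompoundRecord,
    IndicationCatalog,
    InteractionMatrix,
    PanelDefinition,
    ProteinSiteModel,
)


def fingerprint_to_hex(fp: np.ndarray) -> str:
    return np.packbits(fp.astype(np.uint8)).tobytes().hex()


def hex_to_fingerprint(hexstr: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def write_compounds(compounds: Sequence[CompoundRecord], path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "name": [c.name for c in compounds],
            "status": [c.status for c in compounds],
            "n_bits": [c.fingerprint.size for c in compounds],
            "fingerprint_hex": [fingerprint_to_hex(c.fingerprint) for c in compounds],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_compounds(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"fingerprint_hex": str})
    return [
        CompoundRecord(
            str(r.compound_id),
            str(r.name),
            str(r.status),
            hex_to_fingerprint(r.fingerprint_hex, int(r.n_bits)),
        )
        for r in df.itertuples()
    ]


def write_site_models(models: Sequence[ProteinSiteModel], path) -> None:
    payload = {
        "proteins": [
            {
                "protein_id": m.protein_id,
                "sites": [
                    {
                        "site_id": s.site_id,
                        "site_score": s.site_score,
                        "n_bits": int(s.ligand_fingerprints[0].size),
                        "ligands_hex": [fingerprint_to_hex(fp) for fp in s.ligand_fingerprints],
                    }
                    for s in m.sites
                ],
            }
            for m in models
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_site_models(path) -> list:
    payload = json.loads(Path(path).read_text())
    models = []
    for m in payload["proteins"]:
        sites = tuple(
            BindingSite(
                s["site_id"],
                float(s["site_score"]),
                tuple(hex_to_fingerprint(h, int(s["n_bits"])) for h in s["ligands_hex"]),
            )
            for s in m["sites"]
        )
        models.append(ProteinSiteModel(m["protein_id"], sites))
    return models


def write_catalog(catalog: IndicationCatalog, path) -> None:
    rows = [
        (ind.indication_id, cid)
        for ind in sorted(catalog, key=lambda x: x.indication_id)
        for cid in sorted(ind.approved_compound_ids)
    ]
    pd.DataFrame(rows, columns=["indication_id", "compound_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path) -> IndicationCatalog:
    df = pd.read_csv(path, sep="\t")
    return IndicationCatalog.from_pairs(
        zip(df["indication_id"].astype(str), df["compound_id"].astype(str))
    )


def write_matrix(matrix: InteractionMatrix, path, full_precision: bool = False) -> None:
    """Write the matrix as TSV; 6 decimals by default, ``%.17g`` (an exact
    float64 round trip, as the pipeline's cache validation requires) when
    ``full_precision`` is set."""
    fmt = "%.17g" if full_precision else "%.6f"
    matrix.to_frame().to_csv(path, sep="\t", float_format=fmt, index_label="compound_id")


def read_matrix(path) -> InteractionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return InteractionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def write_panel(panel: PanelDefinition, path) -> None:
    Path(path).write_text("\n".join(panel.protein_ids) + "\n")


def read_panel(path, panel_id: str | None = None) -> PanelDefinition:
    pids = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    return PanelDefinition(panel_id or Path(path).stem, tuple(pids))
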