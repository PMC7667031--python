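"""Plain-text readers and writers for every pipeline artifact.

Everything is TSV/CSV/JSON so outputs diff cleanly and rerun byte-identically
under a fixed seed (floats are written with a fixed ``%.12g`` format).  The
network JSON schema is versioned.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import AbundanceMatrix, GeneRecord, Ontology
from .chemostat import ChemostatRecord
from .ecfba import EnzymeInfo, MetabolicNetwork, Reaction
from .errors import DataError

FLOAT_FMT = "%.12g"
NETWORK_SCHEMA_VERSION = 1


# ------------------------------------------------------------------ matrices

def write_matrix_tsv(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.data.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix_tsv(path: str | Path, layer: str, units: str) -> AbundanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    return AbundanceMatrix(frame, layer=layer, units=units)


def write_frame_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def read_frame_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- annotation

def write_annotation_tsv(annotation: list[GeneRecord], path: str | Path) -> None:
    rows = [{
        "gene_id": r.gene_id,
        "mol_weight_kda": r.mol_weight,
        "n_theoretical_peptides": r.n_theoretical_peptides,
        "processes": ";".join(sorted(r.processes)),
    } for r in annotation]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_annotation_tsv(path: str | Path) -> list[GeneRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        GeneRecord(
            gene_id=row["gene_id"],
            mol_weight=float(row["mol_weight_kda"]),
            n_theoretical_peptides=int(row["n_theoretical_peptides"]),
            processes=frozenset(p for p in str(row["processes"]).split(";") if p),
        )
        for _, row in frame.iterrows()
    ]


# ----------------------------------------------------------------- gene sets

def write_gene_sets_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """GMT-style: set_id <tab> description <tab> member ids."""
    with open(path, "w") as fh:
        for set_id, (desc, members) in sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_gene_sets_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DataError(f"malformed gene-set line: {line[:60]!r}")
        sets[parts[0]] = (parts[1], parts[2:])
    return sets


def ontology_from_gene_sets(sets: dict[str, tuple[str, list[str]]]) -> Ontology:
    return Ontology(process_ids=tuple(sets.keys()))


# ------------------------------------------------------------------- network

def write_network_json(network: MetabolicNetwork, path: str | Path) -> None:
    payload = {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "metabolites": [{"id": m, "internal": internal}
                        for m, internal in network.metabolites.items()],
        "reactions": [{
            "id": r.id, "stoichiometry": r.stoichiometry,
            "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
            "reversible": r.reversible, "role": r.role,
        } for r in network.reactions],
        "enzymes": {rid: {"enzyme_id": e.enzyme_id, "kcat_per_h": e.kcat,
                          "mw_kda": e.mw}
                    for rid, e in network.enzymes.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_network_json(path: str | Path) -> MetabolicNetwork:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != NETWORK_SCHEMA_VERSION:
        raise DataError(f"unsupported network schema {payload.get('schema_version')!r}")
    return MetabolicNetwork(
        metabolites={m["id"]: bool(m["internal"]) for m in payload["metabolites"]},
        reactions=[Reaction(r["id"], r["stoichiometry"], r["lower_bound"],
                            r["upper_bound"], r["reversible"], r["role"])
                   for r in payload["reactions"]],
        enzymes={rid: EnzymeInfo(e["enzyme_id"], e["kcat_per_h"], e["mw_kda"])
                 for rid, e in payload["enzymes"].items()},
    )


# ----------------------------------------------------------------- chemostat

def write_chemostat_csv(records: list[ChemostatRecord], path: str | Path) -> None:
    compounds = sorted({c for r in records
                        for c in (*r.feed_concentrations, *r.residual_concentrations)})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "strain": r.strain, "dilution_rate": r.dilution_rate,
            "biomass_gdcw_per_l": r.biomass, "product_titer_mg_per_l": r.product_titer,
        }
        for c in compounds:
            row[f"feed_{c}"] = r.feed_concentrations.get(c, "")
            row[f"residual_{c}"] = r.residual_concentrations.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_chemostat_csv(path: str | Path) -> list[ChemostatRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        feed, residual = {}, {}
        for col in frame.columns:
            if col.startswith("feed_") and pd.notna(row[col]) and row[col] != "":
                feed[col[len("feed_"):]] = float(row[col])
            if col.startswith("residual_") and pd.notna(row[col]) and row[col] != "":
                residual[col[len("residual_"):]] = float(row[col])
        records.append(ChemostatRecord(
            strain=row["strain"], dilution_rate=float(row["dilution_rate"]),
            biomass=float(row["biomass_gdcw_per_l"]),
            feed_concentrations=feed, residual_concentrations=residual,
            product_titer=float(row["product_titer_mg_per_l"])))
    return records
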