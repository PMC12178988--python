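"""File formats, run manifests and dataset validation.

All files are tab-delimited text with documented headers:

* map:        ``marker  chrom  pos_cM`` (markers ordered by chromosome
              and position)
* genotypes:  ``id  <marker...>`` with 0/1/2 alternative-allele counts
              (0 = homozygous common-parent)
* haplotypes: long format ``id  haplotype  marker  allele  origin`` —
              the full origin-labelled genome archive
* effects:    ``marker  population  trait  beta``
* phenotypes: ``id  <trait...>``

Every write goes through :func:`write_results`-style manifests: a JSON
snapshot of configuration, seeds, package version and SHA-256 checksums
of the emitted files, sufficient to reproduce a run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genmap import MarkerMap
from .genome import Population
from .genetics import EffectsTable
from .synthetic import PhenotypeTable

__all__ = [
    "read_map", "write_map",
    "read_genotypes", "write_genotypes",
    "read_haplotypes", "write_haplotypes",
    "read_effects", "write_effects",
    "read_phenotypes", "write_phenotypes",
    "read_dataset", "write_results", "write_manifest", "verify_manifest",
]

_SEP = "\t"


class DataFormatError(ValueError):
    """Malformed or inconsistent input data."""


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_SEP)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}")
    return df


def write_map(gmap: MarkerMap, path) -> None:
    gmap.to_frame().to_csv(path, sep=_SEP, index=False)


def read_map(path) -> MarkerMap:
    df = _read_table(Path(path), ["marker", "chrom", "pos_cM"])
    try:
        return MarkerMap.from_frame(df)
    except ValueError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_genotypes(pop: Population, path) -> None:
    df = pd.DataFrame(pop.genotype_matrix(),
                      columns=list(pop.gmap.marker_ids))
    df.insert(0, "id", pop.ids)
    df.to_csv(path, sep=_SEP, index=False)


def read_genotypes(path, gmap: MarkerMap) -> pd.DataFrame:
    """Genotype score matrix (ids as index); validates the 0/1/2 coding."""
    df = _read_table(Path(path), ["id"])
    markers = list(gmap.marker_ids)
    missing = [m for m in markers if m not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: genotypes lack {len(missing)} mapped "
                              f"markers (first: {missing[0]})")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DataFormatError(f"{path}: duplicated individual id {dup!r}")
    X = df[markers].to_numpy()
    bad = ~np.isin(X, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataFormatError(
            f"{path}: genotype {X[r, c]!r} for individual "
            f"{df['id'].iloc[r]!r} at marker {markers[c]!r}; scores must be "
            "0 (hom. common parent), 1 (het) or 2 (hom. alternative)")
    return df.set_index("id")[markers]


def write_haplotypes(pop: Population, path) -> None:
    n, _, L = pop.alleles.shape
    ids = np.repeat(pop.ids, 2 * L)
    hap = np.tile(np.repeat([0, 1], L), n)
    marker = np.tile(pop.gmap.marker_ids, 2 * n)
    pd.DataFrame({
        "id": ids, "haplotype": hap, "marker": marker,
        "allele": pop.alleles.reshape(-1),
        "origin": np.asarray(pop.origin_labels,
                             dtype=object)[pop.origins.reshape(-1)],
    }).to_csv(path, sep=_SEP, index=False)


def read_haplotypes(path, gmap: MarkerMap,
                    origin_labels: tuple[str, ...] = ("S1", "S2"),
                    generation: str = "") -> Population:
    df = _read_table(Path(path),
                     ["id", "haplotype", "marker", "allele", "origin"])
    unknown = set(df["origin"].unique()) - set(origin_labels)
    if unknown:
        raise DataFormatError(f"{path}: unknown origin label(s) {unknown}")
    if not df["allele"].isin((0, 1)).all():
        bad = df.loc[~df["allele"].isin((0, 1))].iloc[0]
        raise DataFormatError(f"{path}: haplotype allele {bad['allele']!r} "
                              f"for {bad['id']!r}; alleles must be 0 or 1")
    ids = df["id"].unique()
    L = gmap.n_markers
    marker_pos = {m: l for l, m in enumerate(gmap.marker_ids)}
    if set(df["marker"].unique()) != set(marker_pos):
        raise DataFormatError(f"{path}: markers do not match the map")
    n = ids.size
    alleles = np.zeros((n, 2, L), dtype=np.uint8)
    origins = np.zeros((n, 2, L), dtype=np.uint8)
    id_pos = {i: k for k, i in enumerate(ids)}
    rows = df["id"].map(id_pos).to_numpy()
    haps = df["haplotype"].to_numpy(dtype=int)
    cols = df["marker"].map(marker_pos).to_numpy()
    origin_code = {lab: k for k, lab in enumerate(origin_labels)}
    alleles[rows, haps, cols] = df["allele"].to_numpy(dtype=np.uint8)
    origins[rows, haps, cols] = df["origin"].map(origin_code).to_numpy()
    return Population(alleles, origins, ids, gmap, generation,
                      tuple(origin_labels))


def write_effects(effects: EffectsTable, path,
                  marker_ids: np.ndarray | None = None) -> None:
    effects.to_frame(marker_ids).to_csv(path, sep=_SEP, index=False)


def read_effects(path, gmap: MarkerMap,
                 populations: tuple[str, ...] | None = None) -> EffectsTable:
    df = _read_table(Path(path), ["marker", "population", "trait", "beta"])
    pops = tuple(populations or pd.unique(df["population"]))
    traits = tuple(pd.unique(df["trait"]))
    missing_pops = set(pops) - set(df["population"].unique())
    if missing_pops:
        raise DataFormatError(
            f"{path}: no marker effects for population(s) "
            f"{sorted(missing_pops)}")
    L = gmap.n_markers
    marker_pos = {m: l for l, m in enumerate(gmap.marker_ids)}
    beta = np.zeros((len(pops), len(traits), L))
    seen = np.zeros((len(pops), len(traits), L), dtype=bool)
    for _, row in df.iterrows():
        if row["marker"] not in marker_pos:
            raise DataFormatError(
                f"{path}: marker {row['marker']!r} is not on the map")
        p = pops.index(row["population"])
        m = traits.index(row["trait"])
        l = marker_pos[row["marker"]]
        beta[p, m, l] = float(row["beta"])
        seen[p, m, l] = True
    incomplete = [(pops[p], traits[m])
                  for p in range(len(pops)) for m in range(len(traits))
                  if not seen[p, m].all()]
    if incomplete:
        raise DataFormatError(
            f"{path}: effects incomplete for {incomplete[:3]} (every "
            "population/trait needs a value at every mapped marker)")
    return EffectsTable(beta, pops, traits)


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.to_frame().to_csv(path, sep=_SEP, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_table(Path(path), ["id"])
    traits = [c for c in df.columns if c != "id"]
    if not traits:
        raise DataFormatError(f"{path}: no trait columns")
    return PhenotypeTable(df[traits].to_numpy(dtype=float), tuple(traits),
                          df["id"].to_numpy(dtype=object))


def read_dataset(map_path, haplotype_paths, effects_path,
                 phenotype_path=None,
                 origin_labels: tuple[str, ...] = ("S1", "S2")):
    """Load a full dataset: map, one population per haplotype archive,
    effects and (optionally) phenotypes, cross-validated against each
    other."""
    gmap = read_map(map_path)
    pops = [read_haplotypes(p, gmap, origin_labels, generation="F4")
            for p in haplotype_paths]
    effects = read_effects(effects_path, gmap, origin_labels)
    phen = read_phenotypes(phenotype_path) if phenotype_path else None
    if phen is not None and tuple(phen.traits) != tuple(effects.traits):
        raise DataFormatError(
            f"{phenotype_path}: phenotype traits {phen.traits} do not match "
            f"effect traits {effects.traits}")
    return pops, gmap, effects, phen


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(out_dir, config=None, seeds=None,
                   files: list[str] | None = None) -> Path:
    """Write run metadata: config snapshot, seeds, version, checksums."""
    out_dir = Path(out_dir)
    files = files if files is not None else sorted(
        p.name for p in out_dir.iterdir()
        if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": json.loads(json.dumps(_jsonable(config), default=str)),
        "seeds": json.loads(json.dumps(_jsonable(seeds), default=str)),
        "checksums": {f: _sha256(out_dir / f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def verify_manifest(out_dir) -> bool:
    """Check that the recorded file checksums still match."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name, digest in manifest["checksums"].items():
        if not (out_dir / name).exists() or _sha256(out_dir / name) != digest:
            return False
    return True


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  config=None, seeds=None) -> Path:
    """Write named tables as TSV plus a manifest covering them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(out_dir / fname, sep=_SEP, index=False)
        names.append(fname)
    return write_manifest(out_dir, config=config, seeds=seeds, files=names)
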