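"""Plain-text interchange formats.

PED/MAP writing and reading (PLINK-style: 6 leading PED columns, genotypes
as unordered allele pairs with 1 = major, 2 = minor; phenotype 1 =
unaffected, 2 = affected, 0 = unknown), penetrance-table serialization, the
phenocopy provenance sidecar, and tab-separated result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import CaseControlDataset, PedigreeDataset
from .disease import PenetranceTable
from .genosim import GenotypeMatrix, MarkerInfo


class PedParseError(ValueError):
    """Malformed PED/MAP content; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


_DOSAGE_TO_ALLELES = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2")}


def write_map(markers: list[MarkerInfo], path, chromosome: int = 1) -> None:
    """4-column MAP: chromosome, marker id, genetic distance 0, bp = index*10^3."""
    with open(path, "w") as fh:
        for m in markers:
            fh.write(f"{chromosome}\t{m.id}\t0\t{m.index * 1000}\n")


def read_map(path) -> list[MarkerInfo]:
    """Read a MAP file back into marker stubs (MAF/blocks are not in MAP files;
    both are set to placeholder values)."""
    markers = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedParseError(path, ln, f"expected 4 MAP columns, got {len(parts)}")
            markers.append(
                MarkerInfo(id=parts[1], index=ln - 1, maf=0.5, block_id=0)
            )
    return markers


def _ped_genotype_fields(dosages: np.ndarray) -> str:
    return "\t".join(
        "\t".join(_DOSAGE_TO_ALLELES[int(d)]) for d in dosages
    )


def write_ped_case_control(ds: CaseControlDataset, path) -> None:
    """Case-control rows as singleton families with 0/0 parents."""
    with open(path, "w") as fh:
        for i, iid in enumerate(ds.genotypes.individual_ids):
            pheno = 2 if ds.status[i] == 1 else 1
            fh.write(
                f"F{iid}\t{iid}\t0\t0\t0\t{pheno}\t"
                + _ped_genotype_fields(ds.genotypes.genotypes[i])
                + "\n"
            )


def write_ped_pedigree(ds: PedigreeDataset, path) -> None:
    """Families with father/mother rows (phenotype unknown) then children."""
    with open(path, "w") as fh:
        for fam in ds.families:
            fid = fam.family_id
            fh.write(
                f"{fid}\t{fid}_f\t0\t0\t1\t0\t"
                + _ped_genotype_fields(fam.father_genotype)
                + "\n"
            )
            fh.write(
                f"{fid}\t{fid}_m\t0\t0\t2\t0\t"
                + _ped_genotype_fields(fam.mother_genotype)
                + "\n"
            )
            for i, child in enumerate(fam.children):
                pheno = 2 if child.status == 1 else 1
                fh.write(
                    f"{fid}\t{fid}_c{i}\t{fid}_f\t{fid}_m\t0\t{pheno}\t"
                    + _ped_genotype_fields(fam.child_genotype(i))
                    + "\n"
                )


@dataclass
class PedData:
    """Flat view of a PED/MAP pair: pedigree columns + dosage matrix."""

    table: pd.DataFrame  # family_id, individual_id, father_id, mother_id, sex, phenotype
    genotypes: GenotypeMatrix

    @property
    def status(self) -> np.ndarray:
        """0/1 affection (unknown phenotype mapped to 0 = unaffected-or-unknown)."""
        return (self.table["phenotype"].to_numpy() == 2).astype(np.int8)


def read_ped_map(ped_path, map_path) -> PedData:
    """Read a PED/MAP pair; allele order within a genotype is ignored."""
    markers = read_map(map_path)
    m = len(markers)
    rows, geno = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PedParseError(
                    ped_path,
                    ln,
                    f"expected {6 + 2 * m} fields for {m} markers, got {len(parts)}",
                )
            fam, iid, fat, mot, sex, pheno = parts[:6]
            try:
                pheno_i = int(pheno)
            except ValueError:
                raise PedParseError(ped_path, ln, f"bad phenotype {pheno!r}") from None
            if pheno_i not in (0, 1, 2):
                raise PedParseError(ped_path, ln, f"phenotype must be 0/1/2, got {pheno_i}")
            alleles = parts[6:]
            dosages = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a not in ("1", "2") or b not in ("1", "2"):
                    raise PedParseError(
                        ped_path, ln, f"bad allele pair {a!r}/{b!r} at marker {j}"
                    )
                dosages[j] = (a == "2") + (b == "2")  # unordered: 1 2 == 2 1
            rows.append((fam, iid, fat, mot, int(sex), pheno_i))
            geno.append(dosages)
    table = pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
    )
    g = np.vstack(geno) if geno else np.empty((0, m), dtype=np.int8)
    gm = GenotypeMatrix(g, markers, table["individual_id"].tolist())
    return PedData(table=table, genotypes=gm)


def write_penetrance_table(table: PenetranceTable, path) -> None:
    """27-row plain-text table with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# loci\t{table.loci[0]}\t{table.loci[1]}\t{table.loci[2]}\n")
        fh.write(
            "# maf\t" + "\t".join(repr(float(v)) for v in table.maf) + "\n"
        )
        fh.write(f"# achieved_or\t{float(table.achieved_or)!r}\n")
        fh.write(f"# marginal_dev\t{float(table.marginal_dev)!r}\n")
        fh.write(f"# seed\t{table.seed}\n")
        fh.write("g1\tg2\tg3\tpenetrance\n")
        for g1 in range(3):
            for g2 in range(3):
                for g3 in range(3):
                    fh.write(f"{g1}\t{g2}\t{g3}\t{float(table.cells[g1, g2, g3])!r}\n")


def read_penetrance_table(path) -> PenetranceTable:
    meta: dict[str, list[str]] = {}
    cells = np.zeros((3, 3, 3))
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                meta[parts[0]] = parts[1:]
            elif line and line[0].isdigit():
                g1, g2, g3, pen = line.split()
                cells[int(g1), int(g2), int(g3)] = float(pen)
    seed_raw = meta.get("seed", ["None"])[0]
    return PenetranceTable(
        loci=tuple(meta["loci"]),
        cells=cells,
        maf=np.array([float(v) for v in meta["maf"]]),
        achieved_or=float(meta["achieved_or"][0]),
        marginal_dev=float(meta["marginal_dev"][0]),
        seed=None if seed_raw == "None" else int(seed_raw),
    )


def write_phenocopy_sidecar(ds: CaseControlDataset, path) -> None:
    """Provenance sidecar: individual id, method, source model id."""
    with open(path, "w") as fh:
        fh.write("individual_id\tmethod\tsource_model\n")
        for i, flag in enumerate(ds.phenocopy):
            if flag:
                method, _, source = str(flag).partition(":")
                fh.write(f"{ds.genotypes.individual_ids[i]}\t{method}\t{source or 'NA'}\n")


def write_results_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(entries: dict, path) -> None:
    """Flat key=value manifest, deterministically ordered."""
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")


def read_manifest(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                out[key] = value
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
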