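"""Persistence: HDF5 population containers, VCF/trait/pedigree text exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genome import GenomeMap
from .population import Population
from .trait import TraitArchitecture


def save_population_h5(path, population: Population, gmap: GenomeMap) -> None:
    """Binary container: haplotype matrix plus genome-map tables."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("population")
        grp.create_dataset("haplotypes", data=population.haplotypes,
                           compression="gzip", compression_opts=4)
        grp.create_dataset("ids", data=population.ids)
        str_dt = h5py.string_dtype()
        grp.create_dataset("pool", data=population.pool.astype(object), dtype=str_dt)
        grp.create_dataset("role", data=population.role.astype(object), dtype=str_dt)
        grp.create_dataset("generation", data=population.generation)
        gm = fh.create_group("genome_map")
        gm.create_dataset("lengths_cM", data=gmap.lengths_cM)
        gm.create_dataset("site_class", data=gmap.site_class)
        for c, pos in enumerate(gmap.positions):
            gm.create_dataset(f"positions/{c}", data=pos)


def load_population_h5(path) -> tuple[Population, GenomeMap]:
    with h5py.File(path, "r") as fh:
        grp = fh["population"]
        pop = Population(
            ids=grp["ids"][:],
            haplotypes=grp["haplotypes"][:],
            pool=grp["pool"][:].astype("U4"),
            role=grp["role"][:].astype("U8"),
            generation=grp["generation"][:],
        )
        gm = fh["genome_map"]
        n_chrom = gm["lengths_cM"].shape[0]
        gmap = GenomeMap(
            lengths_cM=gm["lengths_cM"][:],
            positions=[gm[f"positions/{c}"][:] for c in range(n_chrom)],
            site_class=gm["site_class"][:],
        )
    return pop, gmap


def export_vcf(path, population: Population, gmap: GenomeMap,
               sites: np.ndarray | None = None) -> None:
    """Write diploid genotypes at the SNP panel (default) as VCF 4.2 text.

    One contig per chromosome; positions are genetic-map coordinates scaled
    to integers as round(cM x 10^4), bumped minimally to stay strictly
    increasing after rounding.
    """
    if sites is None:
        sites = gmap.snp_indices
    sites = np.asarray(sites)
    chrom_of = gmap.chrom_of_site[sites]
    pos_cm = gmap.flat_positions[sites]
    haps = population.haplotypes[:, :, sites]
    names = [f"ind{int(i)}" for i in population.ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rrsim\n")
        for c, length in enumerate(gmap.lengths_cM):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(round(length * 1e4)) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        last_pos = {}
        for k in range(sites.size):
            c = int(chrom_of[k])
            pos = max(int(round(pos_cm[k] * 1e4)), last_pos.get(c, 0) + 1)
            last_pos[c] = pos
            gts = "\t".join(f"{haps[i, 0, k]}|{haps[i, 1, k]}" for i in range(len(population)))
            fh.write(f"chr{c + 1}\t{pos}\tsite{int(sites[k])}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def export_trait_table(path, arch: TraitArchitecture, gmap: GenomeMap,
                       meta_path=None) -> None:
    """Tabular QTN effects plus scalar metadata (scaling, intercept, Ve)."""
    q = gmap.qtn_indices
    df = pd.DataFrame({
        "qtn_id": q,
        "chromosome": gmap.chrom_of_site[q] + 1,
        "position_cM": gmap.flat_positions[q],
        "additive_effect": arch.additive_effects,
        "dominance_degree": arch.dominance_degrees,
        "dominance_effect": arch.dominance_effects,
    })
    df.to_csv(path, index=False)
    meta = {
        "scaling_constant": arch.scaling_constant,
        "intercept": arch.intercept,
        "env_variance": arch.env_variance,
    }
    if meta_path is None:
        meta_path = Path(path).with_suffix(".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def export_marker_effects(path, model, gmap: GenomeMap) -> None:
    """Estimated RR-BLUP marker effects as a table (SNP id, u_hat, d_hat)."""
    s = gmap.snp_indices
    pd.DataFrame({
        "snp_id": s,
        "chromosome": gmap.chrom_of_site[s] + 1,
        "position_cM": gmap.flat_positions[s],
        "additive_effect": model.u,
        "dominance_effect": model.d,
    }).to_csv(path, index=False)


def export_training_set(genotype_path, phenotype_path, ts) -> None:
    """Training set as genotype-matrix and phenotype-vector text files."""
    header = ",".join(f"snp{j}" for j in range(ts.n_markers))
    np.savetxt(genotype_path, ts.G, fmt="%d", delimiter=",", header=header,
               comments="")
    pd.DataFrame({"cycle": ts.cycle_tags, "phenotype": ts.y}).to_csv(
        phenotype_path, index=False)


def export_pedigree(path, population: Population) -> None:
    """Four-column text pedigree: individual, mother, father, generation."""
    mothers = population.mothers if population.mothers is not None else np.zeros(len(population), dtype=np.int64)
    fathers = population.fathers if population.fathers is not None else np.zeros(len(population), dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("individual\tmother\tfather\tgeneration\n")
        for i in range(len(population)):
            fh.write(f"{population.ids[i]}\t{mothers[i]}\t{fathers[i]}\t"
                     f"{population.generation[i]}\n")
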