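"""Read and write a ResourceBundle as a directory of plain-text files.

Layout::

    bundle/
      risk_snps.tsv   ld.tsv          genes.bed        consequences.tsv
      eqtl.tsv        textmining.tsv  ppi_seed.tsv     somatic.gmt
      ko_categories.gmt   functional_terms.gmt
      snp_universe.tsv    network.tsv    drugs.tsv    meta.yaml
      peaks/<cell type>.bed

Every file uses the formats of :mod:`locus2drug.model_io`; peak BED file
names carry the cell-type name.  ``write_bundle`` then ``read_bundle``
round-trips the bundle.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import model_io as mio
from .chromatin import PeakSet
from .model_io import BedInterval, GeneModel, ResourceBundle


def write_bundle(bundle: ResourceBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_gwas_table(bundle.risk_snps, out / "risk_snps.tsv")
    mio.write_ld_table(bundle.ld, out / "ld.tsv")
    gene_ivs: dict[str, list[BedInterval]] = {}
    for g in bundle.genes:
        gene_ivs.setdefault(g.chrom, []).append(
            BedInterval(g.chrom, g.start, g.end, g.symbol))
    mio.write_bed(gene_ivs, out / "genes.bed")
    bundle.consequences.to_csv(out / "consequences.tsv", sep="\t",
                               index=False)
    bundle.eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    mio.write_gene_pvalues(bundle.textmining_p, out / "textmining.tsv")
    mio.write_gene_pvalues(bundle.ppi_seed_p, out / "ppi_seed.tsv")
    mio.write_gene_sets({"somatic": bundle.somatic_genes},
                        out / "somatic.gmt")
    mio.write_gene_sets(bundle.ko_categories, out / "ko_categories.gmt")
    mio.write_gene_sets(bundle.functional_terms,
                        out / "functional_terms.gmt")
    mio.write_snp_universe(bundle.snp_universe, out / "snp_universe.tsv")
    mio.write_edge_list(bundle.network, out / "network.tsv")
    df = bundle.drugs.copy()
    df["crc_approved"] = df["crc_approved"].astype(int)
    df.to_csv(out / "drugs.tsv", sep="\t", index=False)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for name, ps in bundle.peaks.items():
        mio.write_bed(ps.intervals, peaks_dir / f"{name}.bed")
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump({"gene_universe_n": bundle.gene_universe_n}, fh)


def read_bundle(bundle_dir: str | Path) -> ResourceBundle:
    d = Path(bundle_dir)
    genes = []
    for chrom, ivs in mio.read_bed(d / "genes.bed").items():
        genes.extend(GeneModel(iv.name, chrom, iv.start, iv.end)
                     for iv in ivs)
    genes.sort(key=lambda g: (g.chrom, g.start, g.symbol))
    peaks = {}
    peaks_dir = d / "peaks"
    if peaks_dir.is_dir():
        for f in sorted(peaks_dir.glob("*.bed")):
            peaks[f.stem] = PeakSet(f.stem, mio.read_bed(f))
    meta = {}
    if (d / "meta.yaml").exists():
        with open(d / "meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}
    return ResourceBundle(
        risk_snps=mio.read_gwas_table(d / "risk_snps.tsv"),
        ld=mio.read_ld_table(d / "ld.tsv"),
        genes=genes,
        consequences=mio.read_consequence_table(d / "consequences.tsv"),
        eqtl=mio.read_eqtl_table(d / "eqtl.tsv"),
        textmining_p=mio.read_gene_pvalues(d / "textmining.tsv"),
        ppi_seed_p=mio.read_gene_pvalues(d / "ppi_seed.tsv"),
        somatic_genes=mio.read_gene_sets(d / "somatic.gmt")["somatic"],
        ko_categories=mio.read_gene_sets(d / "ko_categories.gmt"),
        functional_terms=mio.read_gene_sets(d / "functional_terms.gmt"),
        peaks=peaks,
        snp_universe=mio.read_snp_universe(d / "snp_universe.tsv"),
        network=mio.read_edge_list(d / "network.tsv"),
        drugs=mio.read_drug_table(d / "drugs.tsv"),
        gene_universe_n=meta.get("gene_universe_n"))
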