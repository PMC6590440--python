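"""Published reference values for the 14 lycophyte plastomes.

These are the printed per-genome statistics (lengths in bp, GC in %,
unique gene/intron counts) and GenBank accessions used to validate the
pipeline when the original records are available locally.  The package
never downloads them; drop the GenBank flat files into
``data/external/plastomes/<accession>.gb`` to enable the comparisons.
"""

from __future__ import annotations

# taxon -> accession of the annotated plastome record.  The assignment of
# the eight new accessions to species follows submission order and is not
# load-bearing: local records are identified by their sequence length
# (unique across the 14 genomes), not by file name.
ACCESSIONS: dict[str, str] = {
    "Dobs": "MH549637",
    "Ddig": "MH549638",
    "Lcla": "MH549641",
    "Hluc1": "AY660566",
    "Hluc2": "MH549640",
    "Hser": "KX426071",
    "Ifla": "GU191333",
    "Imal": "MH549639",
    "Ipie": "MH549642",
    "Skra": "MH549643",
    "Slep": "MK089531",
    "Smoe": "HM173080",
    "Stam": "MG272484",
    "Sunc": "AB197035",
}

# per-genome characteristics: length, repeat, LSC, SSC (bp);
# GC total/repeat/LSC/SSC (%); unique gene counts and introns
TABLE1: dict[str, dict[str, float]] = {
    "Dobs": dict(length=160877, repeat=17742, lsc=105928, ssc=19465,
                 gc=35.0, gc_repeat=42.3, gc_lsc=33.1, gc_ssc=31.9,
                 genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Ddig": dict(length=159614, repeat=16885, lsc=106400, ssc=19444,
                 gc=35.7, gc_repeat=43.4, gc_lsc=33.8, gc_ssc=32.9,
                 genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Lcla": dict(length=151819, repeat=12417, lsc=105643, ssc=21342,
                 gc=34.5, gc_repeat=46.6, gc_lsc=32.3, gc_ssc=31.3,
                 genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Hluc1": dict(length=154373, repeat=15314, lsc=104088, ssc=19657,
                  gc=36.2, gc_repeat=44.9, gc_lsc=34.4, gc_ssc=32.8,
                  genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Hluc2": dict(length=154368, repeat=15314, lsc=104083, ssc=19657,
                  gc=36.3, gc_repeat=44.9, gc_lsc=34.4, gc_ssc=32.8,
                  genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Hser": dict(length=154176, repeat=15313, lsc=103892, ssc=19658,
                 gc=36.3, gc_repeat=44.9, gc_lsc=34.4, gc_ssc=32.8,
                 genes=122, protein=87, rrna=4, trna=31, introns=22),
    "Ifla": dict(length=145303, repeat=13118, lsc=91862, ssc=27205,
                 gc=37.9, gc_repeat=48.0, gc_lsc=36.4, gc_ssc=33.4,
                 genes=118, protein=82, rrna=4, trna=32, introns=21),
    "Imal": dict(length=145535, repeat=13217, lsc=91715, ssc=27386,
                 gc=38.0, gc_repeat=47.9, gc_lsc=36.5, gc_ssc=33.3,
                 genes=118, protein=82, rrna=4, trna=32, introns=21),
    "Ipie": dict(length=145030, repeat=13042, lsc=91748, ssc=27198,
                 gc=38.0, gc_repeat=48.0, gc_lsc=36.5, gc_ssc=32.7,
                 genes=118, protein=82, rrna=4, trna=32, introns=21),
    "Skra": dict(length=129971, repeat=14597, lsc=54728, ssc=46049,
                 gc=52.3, gc_repeat=56.5, gc_lsc=50.9, gc_ssc=51.5,
                 genes=85, protein=71, rrna=4, trna=10, introns=9),
    "Slep": dict(length=114693, repeat=7308, lsc=80625, ssc=19452,
                 gc=51.9, gc_repeat=57.1, gc_lsc=51.2, gc_ssc=51.3,
                 genes=80, protein=64, rrna=4, trna=12, introns=7),
    "Smoe": dict(length=143775, repeat=12114, lsc=83665, ssc=35882,
                 gc=51.0, gc_repeat=55.7, gc_lsc=49.9, gc_ssc=50.5,
                 genes=93, protein=76, rrna=4, trna=13, introns=11),
    "Stam": dict(length=126399, repeat=12831, lsc=53170, ssc=47567,
                 gc=54.0, gc_repeat=55.2, gc_lsc=53.4, gc_ssc=54.0,
                 genes=68, protein=58, rrna=4, trna=6, introns=7),
    "Sunc": dict(length=144170, repeat=12789, lsc=77706, ssc=40886,
                 gc=54.8, gc_repeat=57.5, gc_lsc=54.3, gc_ssc=54.3,
                 genes=93, protein=77, rrna=4, trna=12, introns=11),
}

# repeat orientation of each genome (direct in two Selaginella, else inverted)
ORIENTATION: dict[str, str] = {t: "IR" for t in TABLE1}
ORIENTATION["Skra"] = "DR"
ORIENTATION["Stam"] = "DR"

# terminal-branch synonymous divergence (substitutions/site) of the
# duplicated-gene partitions vs the 51 single-copy genes
DS_VALUES: dict[str, float] = {
    "Skra_sc51": 0.544,
    "Skra_ndhB_psbM_rps7": 0.184,
    "Stam_sc51": 0.285,
    "Stam_rps4": 0.141,
}

# rate-class strings selected for each protein data set
RATE_CLASSES: dict[str, str] = {
    "sc51": "012232",
    "ndhB_psbM_rps7": "012312",
    "rps4": "012012",
}
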