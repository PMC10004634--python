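"""Small built-in reference tables from the published tirabrutinib study.

These are the worked-example inputs the pipeline arithmetic is validated
against: the 13-kinase selectivity panel (IC50 and published fold columns for
four BTK inhibitors), the replicate SILAC ratios of the downregulated
phosphosites reported for the TMD8 and U-2932 cell lines, the published
regulation thresholds, and the top competition-binding inhibition values.

Everything here is plain printed data, parsed lazily into pandas objects.
"""

from __future__ import annotations

import io

import pandas as pd

# IC50 columns (nM, ">" marks right-censoring) and the published fold-selectivity
# columns for BTK (reference) + 13 kinases x 4 compounds.
_KINASE_PANEL_CSV = """\
kinase,tirabrutinib_ic50,tirabrutinib_fold,ibrutinib_ic50,ibrutinib_fold,acalabrutinib_ic50,acalabrutinib_fold,zanubrutinib_ic50,zanubrutinib_fold
BTK,2.78,1,0.256,1,4.95,1,0.285,1
FYN,2220,799,55.0,215,>10000,>2020,1659,5821
LYNa,3490,1255,17.8,70,>10000,>2020,734,2575
LCK,788,283,5.87,23,5204,1051,369,1293
BLK,1280,460,0.155,0.6,2270,459,1.71,6
BMX,3.16,1,0.747,3,45.1,9,1.26,4
EGFR,>10000,>3597,1.71,7,>10000,>2020,10.7,38
ERBB2,8610,3097,3.01,12,370,75,34.8,122
ERBB4,177,64,0.325,1,30.1,6,2.63,9
ITK,>10000,>3597,21.9,86,>10000,>2020,346,1214
JAK3,>10000,>3597,14.5,57,>10000,>2020,811,2846
TXK,54.5,20,4.89,19,273,55,4.59,16
TEC,9.92,4,1.37,5,13.9,3,4.47,16
CSK,449,162,10.7,42,6653,1344,194,680
"""

# Two published fold cells (zanubrutinib LCK and CSK) are not reproducible from
# the rounded IC50 columns above; recomputation gives 1295 and 681.
PANEL_KNOWN_INCONSISTENT = {("zanubrutinib", "LCK"): "1295", ("zanubrutinib", "CSK"): "681"}

# Published linear ratio thresholds (up, down) per cell line at +/- 2.5 sigma.
THRESHOLDS = {"TMD8": (1.472, 0.679), "U-2932": (1.506, 0.664)}

# Phosphosites downregulated in BOTH cell lines: replicate treatment/control
# ratios for each cell line (already harmonized for the label swap).
_SHARED_DOWN_TSV = """\
protein\tgene\tresidue\tposition\tsequence_window\ttmd8_rep1\ttmd8_rep2\tu2932_rep1\tu2932_rep2
Inositol 1,4,5-trisphosphate 3-kinase B\tITPKB\tS\t43\tPRRAVLSPGSVFS\t0.41\t0.48\t0.57\t0.58
Golgi vesicular membrane-trafficking protein p18\tBET1\tS\t50\tTAIKSLSIEIGHE\t0.29\t0.50\t0.57\t0.61
Vesicle-associated membrane protein-associated protein B/C\tVAPB\tS\t158\tIVSKSLSSSLDDT\t0.44\t0.54\t0.66\t0.60
Extracellular signal-regulated kinase 2\tMAPK1\tY\t187\tTGFLTEYVATRWY\t0.34\t0.47\t0.23\t0.41
Beta-adrenergic receptor kinase 1\tADRBK1\tS\t685\tPLVQRGSANGL_\t0.54\t0.38\t0.61\t0.64
"""

# Phosphosites downregulated in TMD8 only ("-" = not quantified in U-2932).
_TMD8_DOWN_TSV = """\
protein\tgene\tresidue\tposition\tsequence_window\ttmd8_rep1\ttmd8_rep2\tu2932_rep1\tu2932_rep2
Extracellular signal-regulated kinase 1\tMAPK3\tY\t204\tTGFLTEYVATRWY\t0.26\t0.42\t-\t-
Proto-oncogene c-RAF kinase\tRAF1\tS\t1055\tACTLTTSPRLPVF\t0.61\t0.61\t-\t-
90 kDa ribosomal protein S6 kinase 1 (RSK1)\tRPS6KA1\tS\t741\tRVRKLPSTTL_\t0.61\t0.59\t1.16\t0.87
Serine/threonine-protein kinase D2 (PKD2)\tPRKD2\tS\t214\tRLGTSESLPCTAE\t0.46\t0.48\t-\t-
Serine/threonine-protein kinase D2 (PKD2)\tPRKD2\tS\t206\tSLASGHSVRLGTS\t0.32\t0.48\t0.86\t0.83
Serine/threonine-protein kinase D2 (PKD2)\tPRKD2\tS\t710\tEKSFRRSVVGTPA\t0.45\t0.56\t0.90\t0.77
PKCnu (PKD3)\tPRKD3\tS\t735\tEKSFRRSVVGTPA\t0.41\t0.43\t0.85\t0.77
Serine/threonine-protein kinase TAO1\tTAOK1\tS\t9\tSTNRAGSLKDPEI\t0.65\t0.43\t1.06\t0.57
Lymphocyte-oriented kinase\tLOK\tS\t13\tRRILRLSTFEKRK\t0.48\t0.60\t0.85\t0.77
Sugen kinase 223\tSGK223\tS\t889\tEKAFKGSGHWLPA\t0.48\t0.47\t-\t-
Serine/threonine-protein kinase QSK\tSIK3\tS\t808\tPLSKQLSADSAEA\t0.47\t0.55\t1.07\t0.97
Receptor-interacting serine/threonine-protein kinase 2\tRIPK2\tS\t531\tVVSRSPSLNLLQN\t0.54\t0.59\t1.03\t0.75
Activating transcription factor 2\tATF2\tT\t69\tVIVADQTPTPTRF\t0.53\t0.53\t-\t-
Activating transcription factor 2\tATF2\tT\t71\tVADQTPTPTRFLK\t0.50\t0.53\t0.99\t0.86
ETS domain-containing protein Elk-1\tELK1\tS\t501\tSTPVVLSPGPQKP\t0.33\t0.48\t-\t-
ETS domain-containing transcription factor ERF\tERF\tS\t327\tVYNYHLSPRAFLH\t0.59\t0.50\t-\t-
ETS translocation variant 3\tETV3\tS\t245\tMYPDPHSPFAVSP\t0.30\t0.28\t-\t-
ETS translocation variant 3\tETV3\tS\t250\tHSPFAVSPIPGRG\t0.30\t0.28\t-\t-
Myb-like protein 2\tBMYB\tT\t487\tQKVVVTTPLHRDK\t0.67\t0.50\t-\t-
Transcription factor RelB\tRELB\tS\t37\tELGALGSPDLSSL\t0.68\t0.59\t0.93\t0.87
Nuclear factor of activated T-cells, cytoplasmic 2\tNFATC2\tS\t759\tQRSKSLSPSLLGY\t0.67\t0.61\t1.14\t1.19
Nuclear factor of activated T-cells, cytoplasmic 2\tNFATC2\tS\t243\tPVPRPASRSSSPG\t0.65\t0.59\t-\t-
MAPKKK 7-interacting protein 2 (TAB2)\tTAB2\tS\t450\tGNNSATSPRVVVT\t0.61\t0.66\t1.05\t0.98
L-plastin\tLCP1\tS\t5\t_MARGSVSDEEM\t0.52\t0.52\t0.90\t0.88
Nuclear cap-binding protein subunit 1\tNCBP\tS\t22\tHKRRKTSDANETE\t0.49\t0.50\t-\t1.04
B-cell adapter for phosphoinositide 3-kinase\tBCAP\tY\t570\tERPGNFYVSSESI\t0.51\t0.41\t-\t-
Astrocytic phosphoprotein PEA-15\tPEA15\tS\t137\tDIIRQPSEEEIIK\t0.35\t0.29\t1.18\t1.03
Sodium/hydrogen exchanger 1\tNHE1\tS\t703\tSRARIGSDPLAYE\t0.55\t0.51\t-\t-
Heat shock 27 kDa protein\tHSP27\tS\t82\tALSRQLSSGVSEI\t0.62\t0.60\t1.09\t0.76
Nuclease-sensitive element-binding protein 1 (YB-1)\tYBX1\tS\t102\tPRKYLRSVGDGET\t0.60\t0.46\t-\t-
40 kDa proline-rich AKT substrate (PRAS40)\tAKT1S1\tT\t246\tPRPRLNTSDFQKL\t0.61\t0.51\t0.84\t0.87
"""

# Competition-binding screen at 300 nM: the five published percent-inhibition
# values above the 65% hit rule, padded with SYNTHETIC below-cutoff kinases
# standing in for the remainder of the 442-kinase panel (not redistributable).
_KINOME_CSV = """\
kinase,pct_ctrl
BTK,3
TEC,7.8
BMX,11
HUNK,11
RIPK2,33
SYNTH_KIN1,35
SYNTH_KIN2,50
SYNTH_KIN3,78
SYNTH_KIN4,92
SYNTH_KIN5,100
"""


def kinase_panel() -> pd.DataFrame:
    """Selectivity panel: IC50 strings and published fold strings per compound."""
    return pd.read_csv(io.StringIO(_KINASE_PANEL_CSV), dtype=str).set_index("kinase")


def _sites(tsv: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(tsv), sep="\t", na_values=["-"])
    for col in ("tmd8_rep1", "tmd8_rep2", "u2932_rep1", "u2932_rep2"):
        df[col] = pd.to_numeric(df[col])
    return df


def downregulated_sites() -> pd.DataFrame:
    """All published downregulated phosphosites (shared + TMD8-only), with
    replicate ratios for both cell lines where quantified."""
    return pd.concat(
        [_sites(_SHARED_DOWN_TSV), _sites(_TMD8_DOWN_TSV)], ignore_index=True
    )


def shared_downregulated_sites() -> pd.DataFrame:
    """The five phosphosites downregulated in both cell lines."""
    return _sites(_SHARED_DOWN_TSV)


def site_table_for_cell_line(cell_line: str) -> pd.DataFrame:
    """Published ratio pairs reshaped into the phosphosite-table dialect."""
    df = downregulated_sites()
    key = {"TMD8": ("tmd8_rep1", "tmd8_rep2"), "U-2932": ("u2932_rep1", "u2932_rep2")}[
        cell_line
    ]
    out = df[["protein", "gene", "position", "residue", "sequence_window"]].copy()
    out["localization_prob"] = 1.0
    out["ratio_rep1"] = df[key[0]]
    out["ratio_rep2"] = df[key[1]]
    return out


def kinome_screen() -> pd.DataFrame:
    """Competition-binding %CTRL values (published hits + synthetic padding)."""
    return pd.read_csv(io.StringIO(_KINOME_CSV))
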