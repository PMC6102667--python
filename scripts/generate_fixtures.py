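"""Regenerate the packaged cnet fixtures from the transcribed model rules.

The published behaviours are asserted before writing: ten fixed points for
the floral-organ network, seven fixed points and the 1764-state G1 basin
for the yeast cell cycle.
"""
from bncana.schemata import LookupTable
from bncana.network import BooleanNetwork, write_cnet, find_attractors

import os
DATA = os.path.join(os.path.dirname(__file__), "..", "src", "bncana", "data")


def lut(name, inputs, fn):
    return LookupTable.from_function(name, inputs, fn)


# --- Arabidopsis thaliana floral-organ GRN (Chaos et al. 2006 lineage) -----
thaliana = BooleanNetwork([
    lut("AP1", ("FT", "LFY", "AG", "TFL1"),
        lambda ft, lfy, ag, tfl1: (not tfl1) and (not ag) and (ft or lfy)),
    lut("AP2", ("TFL1",), lambda tfl1: not tfl1),
    lut("AP3", ("LFY", "UFO", "AP3", "PI", "SEP", "AP1", "AG"),
        lambda lfy, ufo, ap3, pi, sep, ap1, ag:
        (lfy and ufo) or (ap3 and pi and sep and (ap1 or ag))),
    lut("AG", ("AP1", "AP2", "AG", "LFY", "FUL", "TFL1", "WUS", "LUG", "CLF"),
        lambda ap1, ap2, ag, lfy, ful, tfl1, wus, lug, clf:
        (not tfl1) and lfy and (wus or ful or not (ap2 and lug and clf))),
    lut("EMF1", ("LFY",), lambda lfy: not lfy),
    lut("FT", ("EMF1",), lambda emf1: not emf1),
    lut("FUL", ("AP1", "TFL1", "FUL"),
        lambda ap1, tfl1, ful: (not tfl1) and ((not ap1) or ful)),
    lut("LFY", ("TFL1", "EMF1"), lambda tfl1, emf1: (not tfl1) or (not emf1)),
    lut("LUG", (), lambda: 1),
    lut("CLF", (), lambda: 1),
    lut("PI", ("LFY", "AP3", "PI", "SEP", "AP1", "AG"),
        lambda lfy, ap3, pi, sep, ap1, ag:
        (lfy and ap3) or (pi and sep and ap3 and (ap1 or ag))),
    lut("SEP", ("LFY",), lambda lfy: lfy),
    lut("TFL1", ("AP2", "LFY", "EMF1", "AP1"),
        lambda ap2, lfy, emf1, ap1: (not lfy) and emf1 and (not ap1)),
    lut("UFO", ("UFO",), lambda ufo: ufo),
    lut("WUS", ("WUS", "AG", "SEP"),
        lambda wus, ag, sep: wus and (not ag) and (not sep)),
])

atts = find_attractors(thaliana)
assert len(atts) == 10, len(atts)
assert all(a.is_fixed_point for a in atts)

# --- Budding yeast cell cycle (Li et al. 2004 threshold rules) -------------
def thr(pos, neg, hold):
    """Threshold rule: +1 activators, -1 inhibitors, hold-or-decay on ties."""
    def fn(*states):
        npos, nneg = len(pos), len(neg)
        s = sum(states[:npos]) - sum(states[npos:npos + nneg])
        if s > 0:
            return 1
        if s < 0:
            return 0
        return states[npos + nneg] if hold else 0
    return fn


def tnode(name, pos, neg, hold):
    inputs = tuple(pos) + tuple(neg) + ((name,) if hold else ())
    return lut(name, inputs, thr(pos, neg, hold))


yeast = BooleanNetwork([
    lut("Cln3", (), lambda: 0),  # no upstream signal; self-degrading
    tnode("MBF", ("Cln3",), ("Clb12",), hold=True),
    tnode("SBF", ("Cln3",), ("Clb12",), hold=True),
    tnode("Cln12", ("SBF",), (), hold=False),
    tnode("Cdh1", ("Cdc20",), ("Cln12", "Clb56", "Clb12"), hold=True),
    tnode("Swi5", ("Mcm1", "Cdc20"), ("Clb12",), hold=False),
    tnode("Cdc20", ("Clb12", "Mcm1"), (), hold=False),
    tnode("Clb56", ("MBF",), ("Sic1", "Cdc20"), hold=True),
    tnode("Sic1", ("Cdc20", "Swi5"), ("Cln12", "Clb56", "Clb12"), hold=True),
    tnode("Clb12", ("Clb56", "Mcm1"), ("Cdc20", "Sic1", "Cdh1"), hold=True),
    tnode("Mcm1", ("Clb56", "Clb12"), (), hold=False),
])
atts = find_attractors(yeast)
assert len(atts) == 7, len(atts)
g1 = max(atts, key=lambda a: a.basin_size)
assert g1.basin_size == 1764, g1.basin_size
on = {n for n, b in zip(yeast.names, yeast.decode(g1.configurations[0])) if b}
assert on == {"Cdh1", "Sic1"}, on

# --- Drosophila segment polarity, simplified single cell -------------------
# One parasegment cell; neighbouring WG/HH signals and the SLP prepattern
# are aggregated into held external inputs (synthetic simplification of the
# multicellular model).
droso = BooleanNetwork([
    lut("SLP", ("SLP",), lambda s: s),
    lut("nWG", ("nWG",), lambda s: s),
    lut("nHH", ("nHH",), lambda s: s),
    lut("wg", ("CIA", "SLP", "CIR", "wg"),
        lambda cia, slp, cir, wg: ((cia and slp) or (wg and (cia or slp))) and not cir),
    lut("WG", ("wg",), lambda wg: wg),
    lut("en", ("nWG", "SLP"), lambda nwg, slp: nwg and not slp),
    lut("EN", ("en",), lambda en: en),
    lut("hh", ("EN", "CIR"), lambda en, cir: en and not cir),
    lut("HH", ("hh",), lambda hh: hh),
    lut("ptc", ("CIA", "EN", "CIR", "PTC", "HH", "nHH"),
        lambda cia, en, cir, ptc, hh, nhh:
        (cia and not en and not cir) or (ptc and not hh and not nhh)),
    lut("PTC", ("ptc", "PTC", "HH", "nHH"),
        lambda ptc, PTC, hh, nhh: ptc or (PTC and not hh and not nhh)),
    lut("ci", ("EN",), lambda en: not en),
    lut("CI", ("ci",), lambda ci: ci),
    lut("CIA", ("CI", "PTC", "nHH"),
        lambda ci, ptc, nhh: ci and ((not ptc) or nhh)),
    lut("CIR", ("CI", "PTC", "nHH"),
        lambda ci, ptc, nhh: ci and ptc and not nhh),
])

# --- Small control motifs --------------------------------------------------
chain = BooleanNetwork([
    lut("x1", ("x1",), lambda a: a),
    lut("x2", ("x1",), lambda a: a),
    lut("x3", ("x2",), lambda a: a),
])
mutual_inh = BooleanNetwork([
    lut("x1", ("x2",), lambda b: not b),
    lut("x2", ("x1",), lambda a: not a),
])
copy_loop = BooleanNetwork([
    lut("x1", ("x2",), lambda b: b),
    lut("x2", ("x1",), lambda a: a),
])

for fname, net in [
    ("thaliana", thaliana),
    ("budding_yeast", yeast),
    ("drosophila_cell", droso),
    ("motif_chain", chain),
    ("motif_mutual_inhibition", mutual_inh),
    ("motif_copy_loop", copy_loop),
]:
    with open(f"{DATA}/{fname}.cnet", "w") as fh:
        fh.write(write_cnet(net))
    print(fname, "N =", net.N)
print("ok")
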