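"""Regenerate the bundled synthetic germline stand-in library.

Builds each gene from the Kabat consensus template with gene-specific
framework and CDR edits (addressed by Kabat position number), validates
numbering in both schemes and round-trip stability, and rewrites
src/abgraft/data/germline_library.synthetic.fasta.  Run from the repo root.
"""
from abgraft.schemes import get_template
from abgraft.numbering import AntibodySequence, number_sequence, renumber

def typical_base(chain_class):
    """Kabat-template columns without insertion codes, as (label->aa) dict."""
    t = get_template("kabat", chain_class)
    cols = [(c.position, c.consensus_aa, c.region) for c in t.columns
            if c.position.insertion_code is None]
    return cols

# per-gene edits addressed by plain Kabat number -> aa; 'del' removes
GENES = {
  # human heavy: IGHV4-59 / IGHV4-4 carry V71/F78; IGHV2-26 carries K71/V78
  "IGHV4-59": ("heavy", {1:"Q",5:"Q",9:"P",11:"V",13:"Q",23:"K",40:"P",42:"G",71:"V",78:"F",
                          31:"S",32:"S",33:"Y",34:"W",35:"S", 95:"A",96:"R",97:"G",98:"Y",99:"S"}),
  "IGHV2-26": ("heavy", {1:"E",3:"T",5:"K",10:"T",12:"R",18:"T",48:"I",67:"L",71:"K",78:"V",
                          31:"S",32:"N",33:"A",34:"R",35:"M", 95:"A",96:"R",97:"I",98:"H",99:"D"}),
  "IGHV4-4":  ("heavy", {1:"Q",5:"Q",9:"P",13:"Q",17:"T",24:"G",43:"R",70:"S",71:"V",78:"F",
                          31:"S",32:"N",33:"Y",34:"Y",35:"S", 95:"A",96:"R",97:"G",98:"S",99:"T"}),
  # murine heavy of the parental antibody: K71/V78, divergent framework
  "IGHV2-9":  ("heavy", {1:"E",3:"K",5:"K",10:"S",12:"K",15:"S",19:"K",38:"R",43:"K",46:"R",
                          67:"F",71:"K",75:"T",78:"V",81:"N",85:"N",87:"S",93:"V",
                          31:"D",32:"Y",33:"Y",34:"M",35:"N", 95:"G",96:"G",97:"Y",98:"G",99:"S"}),
  # human kappa: S60 / G66
  "IGKV1-16": ("kappa", {3:"Q",9:"S",13:"A",18:"R",42:"K",45:"K",60:"S",66:"G",74:"F",83:"F",
                          24:"R",25:"A",26:"S",28:"G",30:"S", 89:"Q",90:"Q",91:"Y",92:"N",93:"S"}),
  "IGKV1-39": ("kappa", {3:"Q",10:"S",13:"A",17:"E",42:"K",60:"S",63:"S",66:"G",78:"L",85:"T",
                          24:"R",25:"A",26:"S",28:"S",30:"S", 89:"Q",90:"Q",91:"S",92:"Y",93:"S"}),
  "IGKV1-6":  ("kappa", {3:"Q",9:"S",14:"S",21:"L",42:"K",60:"S",66:"G",70:"E",80:"A",
                          24:"R",25:"A",26:"S",28:"G",30:"I", 89:"L",90:"Q",91:"D",92:"Y",93:"N"}),
  # murine kappa of the parental antibody: K60 / R66, divergent framework
  "IGKV9-124":("kappa", {3:"V",7:"T",9:"A",11:"M",15:"L",17:"D",20:"S",40:"S",42:"S",45:"K",
                          58:"I",60:"K",63:"T",66:"R",70:"D",76:"N",80:"S",83:"L",
                          24:"K",25:"A",26:"S",28:"N",30:"V", 89:"Q",90:"Q",91:"Y",92:"D",93:"E"}),
}

records = []
for gene, (cc, edits) in GENES.items():
    cols = typical_base(cc)
    seq = []
    for pos, aa, region in cols:
        if region == "FR4":
            continue  # V gene ends before FR4 (J segment supplies it)
        aa2 = edits.get(pos.number, aa)
        seq.append(aa2)
    s = "".join(seq)
    aseq = AntibodySequence(gene, cc, s)
    nk = number_sequence(aseq, "kabat")
    ni = number_sequence(aseq, "imgt")
    # validate: edits landed where addressed
    pm = {p.number: aa for p, aa in nk.positions if p.insertion_code is None}
    for num, aa in edits.items():
        assert pm[num] == aa, (gene, num, aa, pm[num])
    # round-trip
    rt = renumber(renumber(nk, "imgt"), "kabat")
    assert [p.label for p,_ in rt.positions] == [p.label for p,_ in nk.positions], gene
    tag = "synthetic stand-in, consensus-derived, not an IMGT allele"
    records.append((gene, cc, tag, s))
    print(gene, cc, len(s), "ok")

with open("src/abgraft/data/germline_library.synthetic.fasta", "w") as fh:
    for gene, cc, tag, s in records:
        fh.write(f">{gene}|{cc}|{tag}\n")
        for i in range(0, len(s), 60):
            fh.write(s[i:i+60] + "\n")
print("written")
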