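"""One-off generator for the packaged synthetic signature catalogs.

Profiles are block-structured sparse probability vectors: each signature
concentrates on a designated substitution-class / indel-category block so
that refitting is well conditioned. Run from repo root:
    python scripts/make_synthetic_catalogs.py
"""

import numpy as np
import pandas as pd



from ocstrat.genome_features import SBS96_KEYS, DBS78_KEYS, ID83_KEYS  # noqa: E402

rng = np.random.default_rng(911511)


def block_profile(n, block_idx, alpha=0.5, leak=0.01):
    p = np.full(n, leak / n)
    w = rng.dirichlet(np.full(len(block_idx), alpha))
    p[np.asarray(block_idx)] += (1 - leak) * w
    return p / p.sum()


def sbs_block(sub, flank5=None, flank3=None):
    idx = []
    for i, k in enumerate(SBS96_KEYS):
        if f"[{sub}]" not in k:
            continue
        if flank3 is not None and k[-1] != flank3:
            continue
        if flank5 is not None and k[0] != flank5:
            continue
        idx.append(i)
    return idx


sbs = {
    "SBS1": block_profile(96, sbs_block("C>T", flank3="G"), alpha=1.0),
    "SBS3": block_profile(96, list(range(96)), alpha=0.25),
    "SBS5": block_profile(96, sbs_block("T>C"), alpha=0.6),
    "SBS13": block_profile(96, sbs_block("C>G"), alpha=0.6),
    "SBS31": block_profile(96, sbs_block("C>A"), alpha=0.6),
    "SBS35": block_profile(96, sbs_block("T>A"), alpha=0.6),
    "SBS40": block_profile(96, sbs_block("T>G"), alpha=0.6),
    "SBS44": block_profile(
        96, [i for i in sbs_block("C>T") if SBS96_KEYS[i][-1] != "G"], alpha=0.6
    ),
}

dbs_blocks = np.array_split(rng.permutation(78), 5)
dbs = {
    name: block_profile(78, list(block), alpha=0.5)
    for name, block in zip(["DBS2", "DBS4", "DBS5", "DBS7", "DBS11"], dbs_blocks)
}

def id_block(pred):
    return [i for i, k in enumerate(ID83_KEYS) if pred(k)]

ids = {
    "ID1": block_profile(83, id_block(lambda k: ":Ins:" in k and k.startswith("1")), alpha=0.8),
    "ID2": block_profile(83, id_block(lambda k: ":Del:" in k and k.startswith("1")), alpha=0.8),
    "ID5": block_profile(83, id_block(lambda k: ":Ins:R:" in k and not k.startswith("1")), alpha=0.6),
    "ID6": block_profile(83, id_block(lambda k: ":Del:M:" in k and not k.startswith("2")), alpha=0.8),
    "ID8": block_profile(83, id_block(lambda k: k.startswith(("2:Del", "5:Del"))), alpha=0.6),
}


def write(keys, sigs, path):
    df = pd.DataFrame({"Type": keys})
    for name, p in sigs.items():
        df[name] = np.round(p, 8)
    df.to_csv(path, index=False)
    mat = np.array([p for p in sigs.values()])
    cos = (mat @ mat.T) / np.outer(
        np.linalg.norm(mat, axis=1), np.linalg.norm(mat, axis=1)
    )
    np.fill_diagonal(cos, 0)
    print(path, "max pairwise cosine:", cos.max().round(3))


write(SBS96_KEYS, sbs, "src/ocstrat/data/sbs_catalog_synthetic.csv")
write(DBS78_KEYS, dbs, "src/ocstrat/data/dbs_catalog_synthetic.csv")
write(ID83_KEYS, ids, "src/ocstrat/data/id_catalog_synthetic.csv")
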