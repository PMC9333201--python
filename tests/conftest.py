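import numpy as np
import pytest

from pgxstar import simdata, svcall
from pgxstar.catalog import VariantKey, load_gene_models, load_translation_tables
from pgxstar.vario import GenotypeCall, Site, VariantTable


@pytest.fixture(scope="session")
def gene_models():
    return load_gene_models()


@pytest.fixture(scope="session")
def translation_tables():
    return load_translation_tables()


def build_table(samples, records):
    """VariantTable from [(key_str, {sample: (gt, ad?)})] shorthand."""
    sites = []
    for key_str, genos in records:
        key = VariantKey.parse(key_str)
        genotypes = {}
        for sample, spec in genos.items():
            if spec is None:
                genotypes[sample] = GenotypeCall()
            else:
                gt = spec[0]
                ad = spec[1] if len(spec) > 1 else None
                phased = spec[2] if len(spec) > 2 else False
                genotypes[sample] = GenotypeCall(alleles=gt, ad=ad, phased=phased)
        sites.append(Site(key=key, alts=(key.alt,), genotypes=genotypes))
    return VariantTable(samples=samples, sites=sites)


@pytest.fixture
def toy_table_factory():
    return build_table


@pytest.fixture(scope="session")
def gstt1_classifier(translation_tables):
    """Small simulator-trained GSTT1 deletion classifier (3 classes)."""
    gene = "GSTT1"
    model = simdata.build_sim_model(gene)
    classes = sorted(svcall.SV_CLASSES[gene])
    cfg = simdata.SimConfig(mean_depth=250, seed=41)
    feats, labels = simdata.make_training_set(gene, classes, 20, cfg, model=model)
    return svcall.train_sv_classifier(feats, labels, seed=0), model


@pytest.fixture(scope="session")
def cyp2d6_classifier():
    gene = "CYP2D6"
    model = simdata.build_sim_model(gene)
    classes = sorted(svcall.SV_CLASSES[gene])
    cfg = simdata.SimConfig(mean_depth=250, seed=42)
    feats, labels = simdata.make_training_set(gene, classes, 25, cfg, model=model)
    return svcall.train_sv_classifier(feats, labels, seed=0), model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
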