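"""Rule engine: MAF binning, PM2, promotion/demotion, the VUS tree."""

from collections import Counter
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmvus import (
    Classification,
    ClinVarStatus,
    DataStatus,
    EngineConfig,
    EvidenceProfile,
    MafBin,
    VariantRecord,
    classify_maf_bin,
    derive_default_data_status,
    meets_pm2,
    reclassify,
    reclassify_all,
    reclassify_with_trace,
)

CFG = EngineConfig()


class TestMafBin:
    @pytest.mark.parametrize(
        "maf, expected",
        [
            (None, MafBin.VERY_LOW),   # absent from gnomAD = rarest state
            (0.0001, MafBin.VERY_LOW),
            (0.0049, MafBin.VERY_LOW),
            (0.005, MafBin.LOW),       # boundary falls to the middle stratum
            (0.007, MafBin.LOW),
            (0.04, MafBin.LOW),        # boundary falls to the middle stratum
            (0.061, MafBin.MEDIUM),
            (0.827, MafBin.MEDIUM),
        ],
    )
    def test_binning(self, maf, expected):
        assert classify_maf_bin(maf, CFG) == expected

    def test_negative_maf_rejected(self):
        with pytest.raises(ValueError):
            classify_maf_bin(-0.001, CFG)


class TestPm2:
    @pytest.mark.parametrize(
        "maf, expected",
        [(0.0001, True), (0.00006, True), (0.01, True), (0.011, False), (None, True)],
    )
    def test_rarity_criterion(self, maf, expected):
        assert meets_pm2(maf, CFG) is expected

    def test_negative_maf_rejected(self):
        with pytest.raises(ValueError):
            meets_pm2(-1.0, CFG)


class TestDefaultDataStatus:
    @pytest.mark.parametrize(
        "clinvar, expected",
        [
            (ClinVarStatus.NA, DataStatus.NONE),
            (ClinVarStatus.VUSC, DataStatus.CONFLICTING),
            (ClinVarStatus.VUS, DataStatus.SUPPORTIVE),
            (ClinVarStatus.LB, DataStatus.CONFLICTING),
            (ClinVarStatus.B, DataStatus.CONFLICTING),
            (ClinVarStatus.LP, DataStatus.SUPPORTIVE),
            (ClinVarStatus.P, DataStatus.SUPPORTIVE),
        ],
    )
    def test_mapping(self, clinvar, expected):
        assert derive_default_data_status(clinvar) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            derive_default_data_status("maybe")


def _rec(
    gene="TTN",
    maf=None,
    clinvar=ClinVarStatus.NA,
    status=DataStatus.NONE,
    corroborated=False,
    prior=Classification.VUS,
):
    return VariantRecord(
        patient_id="x",
        gene=gene,
        cdna_hgvs="c.1A>G",
        protein_hgvs="p.Met1Val",
        clinvar_status=clinvar,
        maf_percent=maf,
        prior_class=prior,
        evidence=EvidenceProfile(data_status=status, corroborated_pathogenic=corroborated),
    )


class TestReclassify:
    @pytest.mark.parametrize(
        "rec, expected",
        [
            # demotion: common enough to rule out a dominant cardiomyopathy
            (_rec(maf=0.827, clinvar=ClinVarStatus.LB, status=DataStatus.CONFLICTING), Classification.LB),
            # promotion: ClinVar LP, PM2 met, corroborating evidence
            (
                _rec(gene="MYH7", maf=0.00006, clinvar=ClinVarStatus.LP,
                     status=DataStatus.SUPPORTIVE, corroborated=True),
                Classification.LP,
            ),
            # ClinVar LP but no corroboration: stays in the VUS tree
            (
                _rec(maf=None, clinvar=ClinVarStatus.LP, status=DataStatus.SUPPORTIVE),
                Classification.VUS_LP,
            ),
            # conflicting data, low frequency -> benign lean
            (
                _rec(gene="ACTN2", maf=0.027, clinvar=ClinVarStatus.VUSC, status=DataStatus.CONFLICTING),
                Classification.VUS_LB,
            ),
            # conflicting data, very low frequency -> unresolved
            (
                _rec(gene="ACTN2", maf=0.0001, clinvar=ClinVarStatus.VUSC, status=DataStatus.CONFLICTING),
                Classification.VUS,
            ),
            # no data, absent from gnomAD -> deleterious lean
            (_rec(maf=None), Classification.VUS_LP),
            # supportive data at the low-bin boundary -> deleterious lean
            (
                _rec(gene="SCN5A", maf=0.005, clinvar=ClinVarStatus.VUS, status=DataStatus.SUPPORTIVE),
                Classification.VUS_LP,
            ),
        ],
    )
    def test_published_example_patterns(self, rec, expected):
        assert reclassify(rec, CFG) == expected

    def test_non_vus_prior_rejected(self):
        with pytest.raises(ValueError, match="VUS only"):
            reclassify(_rec(prior=Classification.LP), CFG)

    def test_off_panel_gene_stays_vus(self):
        rec = _rec(gene="MYBPC3", maf=None, status=DataStatus.SUPPORTIVE)
        cls, trace = reclassify_with_trace(rec, CFG)
        assert cls == Classification.VUS and trace == "off_panel"

    def test_never_emits_definitive_extremes(self, fixture_records):
        for rec in fixture_records:
            assert reclassify(rec, CFG) not in (Classification.B, Classification.P)

    def test_fixture_tally_matches_published_counts(self, classified_fixture):
        tally = Counter(r.current_class for r in classified_fixture)
        assert tally == {
            Classification.LB: 5,
            Classification.VUS_LB: 27,
            Classification.VUS: 16,
            Classification.VUS_LP: 67,
            Classification.LP: 10,
        }

    def test_fixture_rows_match_published_labels(self, fixture_with_expected, config):
        records, expected = fixture_with_expected
        mismatches = [
            (r.gene, r.cdna_hgvs, got.label, want.label)
            for r, want in zip(records, expected)
            for got in [reclassify(r, config)]
            if got != want
        ]
        assert mismatches == []

    def test_idempotent_on_vus_family_output(self, classified_fixture, config):
        for rec in classified_fixture:
            if rec.current_class.is_vus_family():
                rerun = replace(rec, prior_class=rec.current_class)
                assert reclassify(rerun, config) == rec.current_class

    def test_conservation_one_class_per_record(self, fixture_records, config):
        out = reclassify_all(fixture_records, config)
        assert len(out) == len(fixture_records)
        assert all(r.current_class is not None for r in out)


@st.composite
def engine_inputs(draw):
    gene = draw(st.sampled_from(["TTN", "MYH7", "LMNA", "MYBPC3"]))
    clinvar = draw(st.sampled_from(list(ClinVarStatus)))
    status = draw(st.sampled_from(list(DataStatus)))
    corroborated = draw(st.booleans())
    return gene, clinvar, status, corroborated


@given(
    inputs=engine_inputs(),
    maf_pair=st.tuples(
        st.one_of(st.none(), st.floats(min_value=0, max_value=0.999)),
        st.floats(min_value=0, max_value=0.999),
    ),
)
@settings(max_examples=300, derandomize=True)
def test_maf_monotonicity(inputs, maf_pair):
    """Holding evidence fixed, a higher MAF never moves the call toward
    the pathogenic end of the scale (absent MAF counts as the rarest)."""
    gene, clinvar, status, corroborated = inputs
    lo, hi = maf_pair
    if lo is not None and lo > hi:
        lo, hi = hi, lo
    rec_lo = _rec(gene=gene, maf=lo, clinvar=clinvar, status=status, corroborated=corroborated)
    rec_hi = _rec(gene=gene, maf=hi, clinvar=clinvar, status=status, corroborated=corroborated)
    assert reclassify(rec_hi, CFG) <= reclassify(rec_lo, CFG)


class TestEngineConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="thresholds"):
            EngineConfig(very_low_cutoff=0.05, medium_cutoff=0.04)

    def test_pm2_below_very_low_rejected(self):
        with pytest.raises(ValueError, match="pm2"):
            EngineConfig(pm2_cutoff=0.001)

    def test_yaml_round_trip(self, tmp_path):
        cfg = EngineConfig(lb_promotion_cutoff=0.2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = EngineConfig.from_yaml(path)
        assert loaded == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            EngineConfig.from_dict({"pm3_cutoff": 0.5})
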