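import pytest

from prometa import IdMap, StudyMeta


@pytest.fixture
def als_tissue_meta():
    return StudyMeta(study_id="s1", disease="ALS", stratum="tissue_cell")


@pytest.fixture
def idmap():
    return IdMap(
        entries={"NP_004334": "CALR", "gi|2144": "SOD1", "IPI00021439": "ACTB"},
        overrides={"gi|2144": "SOD1P"},  # manual reassignment shadows the base entry
    )


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)] + ["\t".join(str(c) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
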