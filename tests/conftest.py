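import pytest

from pheroscan.config import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def write_tmp_fasta(tmp_path):
    def _write(name: str, entries: list[tuple[str, str]]):
        path = tmp_path / name
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in entries))
        return path
    return _write
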