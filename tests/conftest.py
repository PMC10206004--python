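import datetime as dt

import pytest

from notescore.annotate import ClinicalNote
from notescore.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_note(text, date=dt.date(2020, 6, 1), role="clinician",
              patient="P1", note_id="N1"):
    return ClinicalNote(note_id, patient, date, role, text)


@pytest.fixture
def note_factory():
    return make_note
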