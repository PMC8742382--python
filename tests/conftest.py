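import pytest

from comorbicalc import load_map


@pytest.fixture(scope="session")
def charlson_map():
    return load_map("charlson")


@pytest.fixture(scope="session")
def elixhauser_map():
    return load_map("elixhauser")


def unique_code(cmap, category: str) -> str:
    """A code flagging ``category`` and no other category of the same index.

    Picks the first prefix (padded to 4 characters with '1' if needed) that
    lights exactly one flag; used by hierarchy tests that need clean
    single-category inputs.
    """
    from comorbicalc import flag_categories

    for cat in cmap.categories:
        if cat.name != category:
            continue
        for prefix in sorted(cat.prefixes):
            for candidate in (prefix, prefix + "1"):
                flags = flag_categories([candidate], cmap)
                if sum(flags.values()) == 1 and flags[category] == 1:
                    return candidate
    raise AssertionError(f"no unique code for {category}")
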