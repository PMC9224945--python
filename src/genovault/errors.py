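"""Exception hierarchy shared across the package."""

from genovault._crypto import IntegrityError

__all__ = [
    "GenovaultError",
    "ContainerError",
    "BoxFormatError",
    "MetadataXmlError",
    "PolicyXmlError",
    "UnsupportedXacmlFeature",
    "ProtectionError",
    "AuthorizationError",
    "Crypt4ghError",
    "Crypt4ghFormatError",
    "HeaderDecryptionError",
    "SegmentAuthenticationError",
    "IntegrityError",
]


class GenovaultError(Exception):
    """Base class for all package errors."""


class ContainerError(GenovaultError):
    """Invalid container operation: missing parent, duplicate id, bad path."""


class BoxFormatError(ContainerError):
    """Packed box stream is malformed: bad magic, truncation, unknown box."""


class MetadataXmlError(GenovaultError):
    """Metadata XML payload could not be parsed."""


class PolicyXmlError(GenovaultError):
    """Policy XML payload could not be parsed."""


class UnsupportedXacmlFeature(PolicyXmlError):
    """The document uses an XACML element outside the supported subset."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"unsupported XACML feature: {element}")


class ProtectionError(GenovaultError):
    """Invalid protection operation (double encryption, missing entry...)."""


class AuthorizationError(GenovaultError):
    """Authorization machinery misuse: unknown operation, missing node."""


class Crypt4ghError(GenovaultError):
    """Base class for envelope codec errors."""


class Crypt4ghFormatError(Crypt4ghError):
    """Envelope bytes are not a valid encrypted file."""


class HeaderDecryptionError(Crypt4ghError):
    """No header packet could be verified with the supplied reader key."""


class SegmentAuthenticationError(Crypt4ghError):
    """A data segment was authenticated by none of the decoded session keys."""
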