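"""Bundled English semiology lexicon and symptom vocabulary.

The default lexicon is a synthetic, code-constructed stand-in for a
curated epilepsy-semiology ontology: 103 primary symptom terms covering
the signs that recur in seizure histories (motor, autonomic, automatism,
sensory/aura, awareness, speech/behavioral), a set of seizure-site
terms, and English synonyms for the commoner surface variants.  Cue
lists (negation, connectives, temporal adverbs) live in the default
rule configuration, not here, so dictionary matching never emits cue
mentions.
"""

from __future__ import annotations

from .lexicon import Lexicon, Term

# (canonical label, synonyms); ids are derived as S001.. in list order.
_SYMPTOMS: list[tuple[str, list[str]]] = [
    ("clonic", ["clonic jerking", "rhythmic jerking"]),
    ("tonic", ["tonic stiffening"]),
    ("tonic-clonic", ["tonic clonic", "generalized convulsion"]),
    ("myoclonic jerk", ["myoclonus", "sudden jerk"]),
    ("atonic drop", ["sudden loss of tone"]),
    ("absence", ["blank spell"]),
    ("staring", ["staring spell", "blank stare"]),
    ("unresponsive to call", ["unresponsive", "no response to calling"]),
    ("eyes rolled up", ["eyes rolling upward", "upward eye rolling"]),
    ("foaming at mouth", ["frothing at the mouth", "foam at the mouth"]),
    ("fall", ["falling down", "drop attack"]),
    ("loss of consciousness", ["unconscious", "lost consciousness"]),
    ("cyanosis", ["turning blue", "bluish lips"]),
    ("tongue biting", ["bit the tongue", "bitten tongue"]),
    ("urinary incontinence", ["wet himself", "wet herself", "loss of bladder control"]),
    ("drooling", ["excessive salivation"]),
    ("lip smacking", ["smacking of the lips"]),
    ("chewing movements", ["chewing motion"]),
    ("swallowing movements", []),
    ("hand rubbing", ["rubbing of the hands"]),
    ("fumbling", ["fumbling movements"]),
    ("picking at clothes", ["picking movements"]),
    ("aura", ["warning feeling"]),
    ("epigastric rising", ["rising sensation in the stomach"]),
    ("deja vu", ["sense of familiarity"]),
    ("jamais vu", []),
    ("fear", ["sudden fright", "intense fear"]),
    ("visual hallucination", ["seeing flashing lights", "seeing colored spots"]),
    ("auditory hallucination", ["hearing ringing", "hearing voices"]),
    ("olfactory hallucination", ["strange smell", "unpleasant odor"]),
    ("gustatory hallucination", ["metallic taste"]),
    ("vertigo", ["spinning sensation"]),
    ("dizziness", ["feeling dizzy", "lightheadedness"]),
    ("headache", ["head pain"]),
    ("nausea", ["feeling sick"]),
    ("vomiting", ["threw up"]),
    ("pallor", ["turning pale", "pale face"]),
    ("flushing", ["facial flushing", "turning red"]),
    ("sweating", ["profuse perspiration", "cold sweat"]),
    ("palpitations", ["racing heart", "pounding heartbeat"]),
    ("piloerection", ["goose bumps"]),
    ("numbness", ["loss of feeling"]),
    ("tingling", ["pins and needles"]),
    ("unilateral jerking", ["one-sided jerking", "jerking on one side"]),
    ("head turning", ["head version", "turning of the head"]),
    ("eye deviation", ["gaze deviation", "eyes deviating"]),
    ("posturing", ["abnormal posture"]),
    ("fencing posture", ["fencer posture"]),
    ("grimacing", ["facial grimace"]),
    ("eye blinking", ["rapid blinking"]),
    ("eyelid fluttering", ["fluttering eyelids"]),
    ("nystagmus", []),
    ("speech arrest", ["unable to speak", "speech stopped"]),
    ("vocalization", ["ictal cry", "crying out", "making sounds"]),
    ("screaming", ["screamed"]),
    ("laughing", ["gelastic outburst", "unprovoked laughter"]),
    ("mumbling", ["muttering"]),
    ("incoherent speech", ["confused speech", "nonsensical speech"]),
    ("confusion", ["confused state", "disoriented thinking"]),
    ("disorientation", ["unaware of surroundings"]),
    ("memory lapse", ["gap in memory", "amnesia for the event"]),
    ("behavioral arrest", ["sudden pause in activity", "motionless pause"]),
    ("wandering", ["aimless walking"]),
    ("agitation", ["agitated behavior"]),
    ("aggression", ["aggressive behavior"]),
    ("restlessness", ["restless movements"]),
    ("tremor", ["trembling", "shaking of the hands"]),
    ("shivering", ["chills"]),
    ("muscle spasm", ["muscle cramping"]),
    ("stiffness", ["rigid body", "body stiffening"]),
    ("limb shaking", ["shaking of the limbs"]),
    ("facial twitching", ["twitching of the face"]),
    ("mouth twitching", ["twitching at the corner of the mouth"]),
    ("body rocking", ["rocking movements"]),
    ("pedaling movements", ["bicycling movements", "leg pedaling"]),
    ("hypermotor activity", ["violent thrashing", "flailing movements"]),
    ("apnea", ["stopped breathing", "breathing pause"]),
    ("breath holding", []),
    ("irregular breathing", ["labored breathing"]),
    ("gasping", ["gasped for air"]),
    ("choking sensation", ["feeling of choking"]),
    ("chest tightness", ["pressure in the chest"]),
    ("abdominal discomfort", ["stomach discomfort", "abdominal pain"]),
    ("pupil dilation", ["dilated pupils"]),
    ("blank expression", ["vacant expression"]),
    ("chapeau de gendarme", ["downturned mouth"]),
    ("dystonic posturing", ["dystonia of the arm"]),
    ("automatism", ["automatic movements"]),
    ("oral automatism", ["oroalimentary automatism"]),
    ("gestural automatism", []),
    ("hypersalivation", []),
    ("enuresis", []),
    ("fecal incontinence", ["loss of bowel control"]),
    ("eye opening", ["forced eye opening"]),
    ("eye closure", ["forced eye closure"]),
    ("head drop", ["head nodding"]),
    ("shoulder shrugging", []),
    ("arm raising", ["elevation of the arm"]),
    ("leg stiffening", []),
    ("finger twitching", []),
    ("toe curling", []),
    ("whole body convulsion", ["generalized shaking", "convulsing all over"]),
    ("grunting", ["grunting sounds"]),
]

_LOCATIONS: list[tuple[str, list[str]]] = [
    ("left arm", ["left upper limb"]),
    ("right arm", ["right upper limb"]),
    ("left leg", ["left lower limb"]),
    ("right leg", ["right lower limb"]),
    ("left hand", []),
    ("right hand", []),
    ("face", []),
    ("mouth", ["perioral region"]),
    ("head", []),
    ("eyes", []),
    ("left side of the body", ["left hemibody"]),
    ("right side of the body", ["right hemibody"]),
    ("trunk", ["torso"]),
    ("shoulder", []),
    ("tongue", []),
    ("neck", []),
]


def default_lexicon() -> Lexicon:
    """Construct the bundled English lexicon (103 symptoms, 16 sites)."""
    terms: dict[str, Term] = {}
    for i, (label, syns) in enumerate(_SYMPTOMS, start=1):
        tid = f"S{i:03d}"
        terms[tid] = Term(
            term_id=tid,
            labels={"en": label},
            synonyms={"en": list(syns)},
            category="symptom",
        )
    for i, (label, syns) in enumerate(_LOCATIONS, start=1):
        tid = f"L{i:03d}"
        terms[tid] = Term(
            term_id=tid,
            labels={"en": label},
            synonyms={"en": list(syns)},
            category="location",
        )
    return Lexicon(
        name="semiokit-default",
        version="1",
        languages=["en"],
        terms=terms,
    )
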