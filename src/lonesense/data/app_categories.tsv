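app_package	category
google_doc	Productivity
office_outlook	Productivity
gmail	Productivity
android_photos	Photography
bazaar	Photography
lightroom	Photography
whatsapp	Communication
android_messenger	Communication
discord	Communication
oneconnect	Lifestyle
tmobile_tuesdays	Lifestyle
samsung_pay	Lifestyle
gearhead	Auto & Vehicles
toyota	Auto & Vehicles
carfax	Auto & Vehicles
couch_surfing	Travel & Local
google_maps	Travel & Local
uber	Travel & Local
duolingo	Education
wonder	Education
canvas	Education
mint	Finance
american_express	Finance
splitwisemobile	Finance
vlc_player	Video Players & Editors
youtube	Video Players & Editors
capcut	Video Players & Editors
snapchat	Social
katana	Social
tiktok	Social
audible	Books & Reference
scribd	Books & Reference
chirp	Books & Reference
slickdeals	Shopping
amazon	Shopping
target	Shopping
fitindex	Health & Fitness
myfitnesspal	Health & Fitness
shealth	Health & Fitness
amazon_prime_video	Entertainment
netflix	Entertainment
hulu	Entertainment
duo	Business
slack	Business
linkedin	Business
spotify	Music & Audio
youtube_music	Music & Audio
soundcloud	Music & Audio
sprint	Tools
android_search_box	Tools
google_mobile_service	Tools
gametools	Unknown
clock	Unknown
calendar	Unknown
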